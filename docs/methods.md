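# Methods

This note records the models implemented in `mmconnect`, the numerical
and design choices made where more than one reasonable option existed,
and what the synthetic-data studies do and do not establish.

## Network construction

**Morphological (KL similarity).**  Per-ROI grey-matter value
distributions are estimated with `scipy.stats.gaussian_kde` (Silverman
bandwidth) and evaluated on a single per-subject grid of 128 (2⁷)
equally spaced points spanning the union range of all of the subject's
values.  One shared grid — rather than a grid per ROI pair — is used
because the symmetric KL sum requires both distributions on common
sample points, and a common grid makes all pairwise entries of one
subject mutually consistent.  The evaluated density is renormalised to a
probability mass vector, floored at ε = 1e-10 and renormalised again:
KL terms are undefined at exact zeros, and the floor bounds the maximal
divergence at roughly 2·ln(1/ε) ≈ 46 nats (KLS ≈ 1e-20) for fully
disjoint distributions.  Logarithms are natural, pairing with
KLS = e^(−D).  Degenerate (zero-variance) ROIs are rejected with the ROI
named in the error, since a density estimate is meaningless there.

**Structural (connection probability).**  Directed probabilities divide
each seed region's fibre counts by its total samples
(samples-per-voxel × voxel count, default 5,000 per voxel); averaging
the two directions gives the symmetric P_ij with a zero diagonal.  No FA
or streamline-count weighting is offered — connection probability is the
only weighting in scope.

**Functional (Pearson).**  Raw correlation values are used as edge
weights and as selection features; no Fisher z-transform is applied
anywhere.  The transform is monotone, so hub ranking would be unchanged;
per-edge t-tests could differ marginally, but the untransformed
convention is kept throughout.

Diagonal conventions: morphological and functional 1 (self-similarity),
structural 0 (no self connection).  Matrices must be symmetric within
1e-12 at construction; file round-trips preserve values to 1e-9.

## Hubs

"Nodal degree" is computed as weighted strength — the sum of absolute
off-diagonal weights — on the weighted group-average network, without
binarisation: no binarisation threshold is defined anywhere in the
workflow, and the networks are natively weighted.  Absolute values stop
negative functional correlations from cancelling positive ones.  The hub
set is the top ⌊0.05·N⌋ nodes (floor; 246 ROIs → 12 hubs), with ties
broken toward the smaller atlas label for determinism.

## Feature selection and NBS

Edge selection uses the pooled-variance (Student) two-sample t-test,
two-sided, with α = 0.01; Welch's variant is available behind a flag but
is not the default.  Edges with zero pooled within-group variance (e.g.
structurally unconnected ROI pairs, whose probability is identically 0)
are flagged degenerate and never selected — no test exists there, so
calibration rates are computed over testable edges only.

The network-based statistic (NBS) thresholds |t| at the two-sided
α-quantile, takes connected components of the suprathreshold edge graph
(via `scipy.sparse.csgraph`), and compares each component's edge count
with the permutation null of the maximal component size under group
label shuffles.  Defaults: primary threshold equal to the selection α
(0.01), 5,000 permutations for reporting runs (smaller counts in
simulation studies), family-wise α = 0.05, fixed recorded seed.  These
settings are this package's own; only the method choice is fixed by the
workflow being reproduced.  NBS is run once on the full sample as the
multiple-comparison report; classification uses the uncorrected per-fold
t-test, keeping the two uses separate.

## Multi-kernel SVM and nested LOOCV

Kernels are linear on the z-scored selected edges of each modality —
the standard choice for high-dimension / low-n connectome features, and
the one that keeps the dual QP exactly reproducible by an independent
solver.  The dual on the combined kernel Σβ_m K_m is solved by LIBSVM
(`sklearn.svm.SVC` with a precomputed kernel); dual feasibility
(Σαᵢyᵢ = 0, 0 ≤ αᵢ ≤ C) is asserted on every trained model.  An exact
active-set enumeration solver (`evaluation.solve_svm_dual_exact`,
exponential in n, for n ≤ ~12) provides an independent check of the
objective and decision values.

Model selection: outer leave-one-out for performance; inside each outer
training set, t-test selection and scaling are refit, and an inner
leave-one-out grid search picks (C, β).  C runs over integer powers of
two in [2⁻⁵, 2⁵] (11 values) by default; β over a simplex grid of step
0.1 (66 points for three modalities).  Ties are broken toward higher
inner accuracy, then smaller C, then the lexicographically smallest β,
making reruns bit-identical.  If a modality selects no edges in some
fold, it contributes an identity kernel (and a zero cross-kernel) with a
warning, so the fold still completes.  Patients are coded +1, so
sensitivity is the patient detection rate.  AUC uses the rank statistic
(ties counted half).

**Consensus connections** are edges selected in every outer fold.
Group means, the two-sided full-sample t-test p-value, and the sign
(positive ⇔ patient mean > control mean) are computed on the full
sample — the per-fold means differ only by one subject — and tables are
sorted by ascending p.

## Synthetic cohorts

The generator emulates the post-preprocessing inputs of a small
two-group study; defaults follow the emulated study design: 22 patients
vs 20 controls, 230 retained time points (240 acquired minus 10
dummies), 5,000 tractography samples per voxel, 50–400 voxels per ROI,
246 ROIs (tests and simulation studies use 20).

* Grey matter: per-ROI truncated normals on (0, 1] (simple, strictly
  inside the valid range, predictable KDE behaviour); base means drawn
  once per cohort from (0.3, 0.7), sd 0.1.  Patient effects shift ROI
  means, perturbing every incident KLS edge.
* Tractography: binomial counts with sparse, ring-distance-decaying
  base probabilities (p₀·e^(−d/2), cut off beyond N/4), reproducing the
  short-range bias of anatomical connectivity without modelling anatomy.
  Patient effects scale edge probabilities by (1+δ).
* BOLD: zero-mean multivariate normals with block-structured target
  correlations (within-block 0.4, between 0.05, blocks of 5), symmetric
  per-subject jitter (sd 0.02), patient shifts of δ on chosen edges, and
  a nearest-positive-definite repair (eigenvalue clip at 1e-6, unit
  diagonal restored) because edited block matrices are often indefinite.

One master seed fans out through `SeedSequence([seed, stage, subject])`
substreams, so any modality of any subject regenerates independently.

Not emulated: hemodynamics, scanner noise spectra, motion, anatomy,
inter-subject variability of tractography probabilities beyond binomial
sampling.  Passing tests therefore demonstrate correctness and
calibration of the *pipeline*, not performance on real MRI.

## Validation studies and their conditions

All studies run on 20-ROI cohorts of 22 vs 20 subjects with a reduced
hyperparameter grid (C ∈ {2⁻², 2²}; β step 0.5 — every simplex vertex is
retained, so the fused model can always emulate the best single
modality).  Problem sizes were chosen to keep a full validation run in
the minutes range on one CPU.

* **Null calibration** (no injected effects): edge-selection rate at
  p < 0.01 over testable edges, averaged over 20 replicate cohorts,
  should sit within 3 standard errors of 1%; the NBS family-wise
  positive rate over 20 cohorts near 5%; mean nested-LOOCV accuracy over
  replicate cohorts within the 95% binomial band of a single 42-fold run
  around 50%.  Note that LOOCV with per-fold selection is known to be
  pessimistically biased and strongly fold-correlated under the null: in
  our measurements single-cohort accuracies scatter roughly between 20%
  and 85% (sd ≈ 20 points) with a mean below 50%, which is why the check
  is placed on the replicate mean against the single-run band rather
  than on a pooled-fold band that would presume independent folds.
* **Recovery**: strong planted effects (grey-matter mean shift +0.2 on
  one ROI over a flat 0.5 base with sd 0.05; δ = ±0.5 on ten structural
  edges; δ = ±0.3 on ten functional edges), 20 replicate cohorts;
  consensus sets must contain ≥80% of the designated edges with ≥90%
  sign agreement.  Morphological truth edges are ten designated edges
  incident to the shifted ROI; their expected sign is negative because
  any mean shift lowers KLS.
* **Fusion**: complementary strong effects (each modality carries its
  own disjoint signal); fused accuracy must stay within 5 points of
  every single-modality accuracy on each seed.

## Known limitations

* The exact-QP oracle is exponential in sample count and only usable on
  toy problems; large-n training correctness rests on LIBSVM.
* Inner leave-one-out on 40-subject folds makes the full default grid
  (11 C × 66 β) expensive (~10⁶ small SVM fits per cohort); the reduced
  grid is recommended for simulation work.
* NBS component p-values are the plain permutation fraction; with few
  permutations the granularity is 1/n_perm.
* The synthetic generator's group labels are index-blocked
  (patients first); all analyses are order-agnostic, but note that any
  accidental index-dependence in future generator changes would
  masquerade as group signal.
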