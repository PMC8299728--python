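"""Study-level evaluation routines and an exact QP reference solver.

This module holds the reusable pieces of the package's own validation
studies, all of which run on synthetic cohorts:

* an exact brute-force solver for the soft-margin SVM dual (active-set
  enumeration; exponential in n, intended for n <= ~12) used as an
  independent oracle for the LIBSVM-backed trainer;
* canonical study configurations (null, planted-effect recovery,
  complementary-effect fusion) at a 20-ROI parcellation with the default
  22-patient / 20-control group sizes;
* the calibration, recovery and fusion studies themselves, which return
  plain numbers so tests and reporting scripts can share one code path.
"""

from __future__ import annotations

import itertools

import numpy as np

from .consensus import consensus_edges
from .mksvm import nested_loocv, selection_fold_masks
from .netio import CohortDataset, edge_index, vectorize
from .networks import (
    build_functional_network,
    build_morphological_network,
    build_structural_network,
)
from .selection import edge_ttest, nbs_correct
from .synthetic import SyntheticConfig, gen_subject, subject_groups

__all__ = [
    "solve_svm_dual_exact",
    "cohort_features",
    "null_config",
    "recovery_config",
    "fusion_config",
    "selection_rate_study",
    "nbs_fwer_study",
    "null_loocv_study",
    "recovery_study",
    "fusion_study",
    "REDUCED_C_GRID",
    "REDUCED_BETA_STEP",
]

# reduced hyperparameter grids for the simulation studies: the C range
# keeps its endpoints' spirit (one small, one large power of two) and the
# beta grid keeps every simplex vertex, so the combined model can always
# emulate the best single modality
REDUCED_C_GRID = np.array([2.0**-2, 2.0**2])
REDUCED_BETA_STEP = 0.5


# ---------------------------------------------------------------------------
# exact dual QP oracle

def solve_svm_dual_exact(
    K: np.ndarray, y: np.ndarray, C: float, tol: float = 1e-8
) -> tuple[np.ndarray, float, float]:
    """Exact solution of the SVM dual by active-set enumeration.

    Maximises ``sum(a) - a' Q a / 2`` with ``Q = yy' * K`` subject to
    ``y'a = 0`` and ``0 <= a <= C`` by enumerating every assignment of
    samples to {lower bound, upper bound, free} and checking the KKT
    conditions.  Returns (alphas, bias, dual objective).  Exponential in
    ``len(y)``; use only on tiny problems.
    """
    y = np.asarray(y, dtype=float)
    K = np.asarray(K, dtype=float)
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K
    idx = np.arange(n)
    # enumerate mostly-free assignments first: typical optima have many
    # interior alphas, so the early-return triggers sooner
    for assign in itertools.product((2, 0, 1), repeat=n):
        assign = np.array(assign)
        free = idx[assign == 2]
        at_up = idx[assign == 1]
        a = np.zeros(n)
        a[at_up] = C
        if len(free):
            kkt = np.zeros((len(free) + 1, len(free) + 1))
            kkt[: len(free), : len(free)] = Q[np.ix_(free, free)]
            kkt[: len(free), -1] = y[free]
            kkt[-1, : len(free)] = y[free]
            rhs = np.concatenate(
                [1.0 - Q[np.ix_(free, at_up)] @ a[at_up], [-y[at_up] @ a[at_up]]]
            )
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            a[free] = sol[:-1]
            nu = sol[-1]
            if (a[free] < -tol).any() or (a[free] > C + tol).any():
                continue
            g = Q @ a - 1.0
            lo_ok = (g[assign == 0] + nu * y[assign == 0] >= -tol).all()
            up_ok = (g[at_up] + nu * y[at_up] <= tol).all()
            if not (lo_ok and up_ok):
                continue
            b = nu
        else:
            if abs(y @ a) > tol:
                continue
            g = Q @ a - 1.0
            # feasible interval for the bias multiplier
            lo_b, hi_b = -np.inf, np.inf
            for i in range(n):
                bound = -g[i] * y[i]  # b*y_i >= -g_i  <=>  y_i-signed bound
                if assign[i] == 0:  # need g + b*y >= 0
                    if y[i] > 0:
                        lo_b = max(lo_b, -g[i])
                    else:
                        hi_b = min(hi_b, g[i])
                else:  # at C: need g + b*y <= 0
                    if y[i] > 0:
                        hi_b = min(hi_b, -g[i])
                    else:
                        lo_b = max(lo_b, g[i])
                del bound
            if lo_b > hi_b + tol:
                continue
            b = (max(lo_b, min(hi_b, 0.0)) + min(hi_b, max(lo_b, 0.0))) / 2.0
            if np.isinf(b):
                b = lo_b if np.isfinite(lo_b) else (hi_b if np.isfinite(hi_b) else 0.0)
        obj = float(a.sum() - 0.5 * a @ Q @ a)
        # the dual is strictly concave on the feasible set for PD kernels,
        # so the first KKT point is the optimum
        return a.copy(), float(b), obj
    raise RuntimeError("active-set enumeration found no KKT point")


# ---------------------------------------------------------------------------
# in-memory cohort assembly

def cohort_features(cfg: SyntheticConfig) -> CohortDataset:
    """Generate a cohort and build all three networks, fully in memory."""
    parc = cfg.parcellation()
    feats: dict[str, list[np.ndarray]] = {
        "morphological": [],
        "structural": [],
        "functional": [],
    }
    labels, ids = [], []
    for k, group in enumerate(subject_groups(cfg)):
        rs, tc, ts = gen_subject(cfg, k, group)
        feats["morphological"].append(vectorize(build_morphological_network(rs, parc)))
        feats["structural"].append(vectorize(build_structural_network(tc, parc)))
        feats["functional"].append(vectorize(build_functional_network(ts, parc)))
        labels.append(1 if group == "patient" else -1)
        ids.append(rs.subject_id)
    return CohortDataset(
        features={m: np.vstack(v) for m, v in feats.items()},
        labels=np.array(labels),
        subject_ids=ids,
        parcellation=parc,
    )


# ---------------------------------------------------------------------------
# canonical study conditions (20-ROI parcellation, 22 vs 20 subjects)

def null_config(seed: int, n_rois: int = 20) -> SyntheticConfig:
    """No injected effects: both groups share every generating parameter."""
    return SyntheticConfig(n_rois=n_rois, seed=seed)


# planted-effect edge lists on the 20-ROI parcellation (0-based indices)
MORPH_EFFECT_ROI = 0
MORPH_TRUTH_EDGES = tuple((0, j) for j in range(1, 11))
STRUCT_TRUTH = tuple(
    (i, j, "structural", 0.5 if k % 2 == 0 else -0.5)
    for k, (i, j) in enumerate(
        [(11, 12), (12, 13), (13, 14), (14, 15), (15, 16),
         (16, 17), (11, 13), (13, 15), (15, 17), (16, 18)]
    )
)
FUNC_TRUTH = tuple(
    (i, j, "functional", 0.3 if k % 2 == 0 else -0.3)
    for k, (i, j) in enumerate(
        [(0, 5), (1, 6), (2, 7), (3, 8), (4, 9),
         (0, 10), (1, 11), (2, 12), (3, 13), (4, 14)]
    )
)


def recovery_config(seed: int) -> SyntheticConfig:
    """Strong planted effects on 10 known edges per modality.

    Morphological effects are injected as a +0.2 grey-matter mean shift
    on one ROI over a flat base mean, which perturbs (lowers) the KLS of
    every edge incident to it; the ten designated truth edges are a
    fixed subset of those.
    """
    return SyntheticConfig(
        n_rois=20,
        seed=seed,
        noise_sd=0.05,
        gm_mean_range=(0.5, 0.5),
        effect_rois=((MORPH_EFFECT_ROI, 0.2),),
        effect_edges=STRUCT_TRUTH + FUNC_TRUTH,
    )


def fusion_config(seed: int) -> SyntheticConfig:
    """Complementary strong effects: each modality carries its own signal."""
    morph_rois = ((0, 0.15), (1, 0.15))
    struct = tuple(
        (i, j, "structural", 0.6)
        for i, j in [(5, 6), (6, 7), (7, 8), (8, 9), (9, 10)]
    )
    func = tuple(
        (i, j, "functional", 0.35)
        for i, j in [(10, 15), (11, 16), (12, 17), (13, 18), (14, 19)]
    )
    return SyntheticConfig(
        n_rois=20,
        seed=seed,
        noise_sd=0.05,
        gm_mean_range=(0.5, 0.5),
        effect_rois=morph_rois,
        effect_edges=struct + func,
    )


# ---------------------------------------------------------------------------
# studies

def selection_rate_study(
    n_replicates: int, seed: int, alpha: float = 0.01
) -> dict[str, tuple[float, float]]:
    """Null edge-selection rate at ``alpha`` per modality.

    Returns {modality: (mean rate over replicate cohorts, SE of the
    mean)}; under a calibrated test the rate is ~alpha.  The rate is
    taken over testable edges only: degenerate edges (zero pooled
    variance, e.g. structurally unconnected ROI pairs) carry no test.
    """
    rates: dict[str, list[float]] = {}
    for r in range(n_replicates):
        ds = cohort_features(null_config(seed=seed + r))
        y = ds.labels
        for mod, X in ds.features.items():
            st = edge_ttest(X[y == 1], X[y == -1], alpha=alpha)
            testable = ~st.degenerate
            rates.setdefault(mod, []).append(
                float(st.selected[testable].mean())
            )
    return {
        m: (float(np.mean(v)), float(np.std(v, ddof=1) / np.sqrt(len(v))))
        for m, v in rates.items()
    }


def nbs_fwer_study(
    n_replicates: int,
    seed: int,
    modality: str = "functional",
    n_perm: int = 500,
    alpha_fwer: float = 0.05,
) -> float:
    """Fraction of null cohorts where NBS declares any significant component."""
    positives = 0
    for r in range(n_replicates):
        ds = cohort_features(null_config(seed=seed + r))
        res = nbs_correct(
            ds.features[modality],
            ds.labels,
            edge_index(ds.parcellation.n_rois),
            n_perm=n_perm,
            alpha_fwer=alpha_fwer,
            seed=seed + 10_000 + r,
        )
        positives += int(len(res.significant) > 0)
    return positives / n_replicates


def null_loocv_study(
    n_replicates: int, seed: int
) -> tuple[float, int]:
    """Pooled nested-LOOCV accuracy over null cohorts.

    Returns (fraction of correct outer-fold predictions, total folds).
    """
    correct = total = 0
    for r in range(n_replicates):
        ds = cohort_features(null_config(seed=seed + r))
        rep = nested_loocv(
            ds.features,
            ds.labels,
            C_grid=REDUCED_C_GRID,
            beta_step=REDUCED_BETA_STEP,
        )
        correct += int((rep.predictions == rep.y_true).sum())
        total += len(rep.y_true)
    return correct / total, total


def _truth_for(cfg: SyntheticConfig) -> dict[str, list[tuple[int, int, str]]]:
    """Ground-truth (i, j, expected_sign) per modality for recovery scoring."""
    truth: dict[str, list[tuple[int, int, str]]] = {
        "morphological": [],
        "structural": [],
        "functional": [],
    }
    for i, j in MORPH_TRUTH_EDGES:
        truth["morphological"].append((i, j, "negative"))  # shift lowers KLS
    for i, j, mod, delta in cfg.effect_edges:
        truth[mod].append((min(i, j), max(i, j), "positive" if delta > 0 else "negative"))
    return truth


def recovery_study(n_replicates: int, seed: int) -> tuple[float, float]:
    """Consensus recovery of planted edges and sign agreement.

    For each replicate cohort, per-outer-fold t-test masks are
    intersected into consensus sets; returns (fraction of planted edges
    present in consensus, fraction of recovered edges whose sign matches
    the injected direction), both pooled over replicates and modalities.
    """
    recovered = planted = signs_ok = signs_total = 0
    for r in range(n_replicates):
        cfg = recovery_config(seed=seed + r)
        ds = cohort_features(cfg)
        idx = edge_index(cfg.n_rois)
        flat = {(i, j): k for k, (i, j) in enumerate(idx.pairs)}
        masks = selection_fold_masks(ds.features, ds.labels, alpha_select=0.01)
        truth = _truth_for(cfg)
        y = ds.labels
        for mod, edges_expected in truth.items():
            _, cons = consensus_edges(masks[mod])
            X = ds.features[mod]
            mp = X[y == 1].mean(axis=0)
            mc = X[y == -1].mean(axis=0)
            for i, j, expected_sign in edges_expected:
                e = flat[(i, j)]
                planted += 1
                if cons[e]:
                    recovered += 1
                    signs_total += 1
                    got = "positive" if mp[e] > mc[e] else "negative"
                    signs_ok += int(got == expected_sign)
    rec_rate = recovered / planted if planted else float("nan")
    sign_rate = signs_ok / signs_total if signs_total else float("nan")
    return rec_rate, sign_rate


def fusion_study(seeds: list[int]) -> dict[str, list[float]]:
    """Single-modality vs 3-kernel accuracies on complementary-effect cohorts.

    Returns {'morphological': [...], 'structural': [...], 'functional':
    [...], 'combined': [...]} with one accuracy (percent) per seed.
    """
    out: dict[str, list[float]] = {
        "morphological": [],
        "structural": [],
        "functional": [],
        "combined": [],
    }
    for s in seeds:
        ds = cohort_features(fusion_config(seed=s))
        for mod in ("morphological", "structural", "functional"):
            rep = nested_loocv(
                {mod: ds.features[mod]},
                ds.labels,
                C_grid=REDUCED_C_GRID,
                beta_step=REDUCED_BETA_STEP,
            )
            out[mod].append(rep.accuracy)
        rep = nested_loocv(
            ds.features,
            ds.labels,
            C_grid=REDUCED_C_GRID,
            beta_step=REDUCED_BETA_STEP,
        )
        out["combined"].append(rep.accuracy)
    return out
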