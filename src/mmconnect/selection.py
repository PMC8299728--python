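"""Edge-wise feature selection and network-based-statistic correction.

Selection is the two-sample Student t-test on each edge feature with a
p < 0.01 default; the network-based statistic (NBS) controls the
family-wise error over edges by comparing the size (edge count) of
suprathreshold connected components against a permutation null of the
maximal component size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .netio import EdgeIndex

__all__ = ["EdgeStats", "NBSResult", "edge_ttest", "nbs_correct", "pooled_tstats"]

ALPHA_DEFAULT = 0.01


@dataclass
class EdgeStats:
    """Per-edge two-sample t statistics and selection decisions.

    ``degenerate`` marks edges with zero pooled within-group variance;
    their t and p are NaN and they are never selected.
    """

    t: np.ndarray
    p: np.ndarray
    mean_patient: np.ndarray
    mean_control: np.ndarray
    selected: np.ndarray
    degenerate: np.ndarray
    alpha: float
    df: int


@dataclass
class NBSResult:
    """Suprathreshold components and their permutation FWER p-values."""

    primary_threshold: float  # |t| cutoff
    components: list[np.ndarray]  # edge-index arrays, one per component
    component_sizes: np.ndarray  # edge counts
    component_pvalues: np.ndarray
    n_permutations: int
    seed: int
    alpha_fwer: float

    @property
    def significant(self) -> list[np.ndarray]:
        return [
            c
            for c, p in zip(self.components, self.component_pvalues)
            if p < self.alpha_fwer
        ]


def pooled_tstats(
    x1: np.ndarray, x2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pooled-variance two-sample t over feature columns.

    Returns (t, degenerate); degenerate features (zero pooled variance)
    carry t = NaN.
    """
    n1, n2 = len(x1), len(x2)
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    ss1 = ((x1 - m1) ** 2).sum(axis=0)
    ss2 = ((x2 - m2) ** 2).sum(axis=0)
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    degenerate = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    t[degenerate] = np.nan
    return t, degenerate


def edge_ttest(
    features_patients: np.ndarray,
    features_controls: np.ndarray,
    alpha: float = ALPHA_DEFAULT,
    equal_var: bool = True,
) -> EdgeStats:
    """Two-sided two-sample t-test per edge; selected iff p < alpha.

    ``equal_var=False`` switches to Welch's t (Satterthwaite df).
    """
    x1 = np.atleast_2d(np.asarray(features_patients, dtype=float))
    x2 = np.atleast_2d(np.asarray(features_controls, dtype=float))
    if x1.shape[1] != x2.shape[1]:
        raise ValueError("groups have different edge counts")
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if equal_var:
        t, degenerate = pooled_tstats(x1, x2)
        df = len(x1) + len(x2) - 2
        with np.errstate(invalid="ignore"):
            p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        res = stats.ttest_ind(x1, x2, axis=0, equal_var=False)
        t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
        degenerate = ~np.isfinite(t)
        t = np.where(degenerate, np.nan, t)
        p = np.where(degenerate, np.nan, p)
        df = len(x1) + len(x2) - 2
    selected = np.zeros(x1.shape[1], dtype=bool)
    ok = ~degenerate
    selected[ok] = p[ok] < alpha
    return EdgeStats(
        t=t,
        p=p,
        mean_patient=x1.mean(axis=0),
        mean_control=x2.mean(axis=0),
        selected=selected,
        degenerate=degenerate,
        alpha=alpha,
        df=df,
    )


def _components_above(
    supra: np.ndarray, edges: EdgeIndex
) -> tuple[list[np.ndarray], np.ndarray]:
    """Connected components of the suprathreshold edge graph.

    Returns per-component edge-index arrays and their edge counts.
    """
    n = edges.n_rois
    which = np.flatnonzero(supra)
    if len(which) == 0:
        return [], np.array([], dtype=int)
    r, c = edges.rows[which], edges.cols[which]
    adj = sparse.coo_matrix(
        (np.ones(len(which)), (r, c)), shape=(n, n)
    )
    _, node_label = connected_components(adj, directed=False)
    comp_of_edge = node_label[r]  # both endpoints share a label
    comps: list[np.ndarray] = []
    for lab in np.unique(comp_of_edge):
        comps.append(which[comp_of_edge == lab])
    sizes = np.array([len(c) for c in comps], dtype=int)
    order = np.argsort(-sizes)
    return [comps[k] for k in order], sizes[order]


def nbs_correct(
    features: np.ndarray,
    labels: np.ndarray,
    edges: EdgeIndex,
    primary_p: float = 0.01,
    n_perm: int = 5000,
    alpha_fwer: float = 0.05,
    seed: int = 0,
) -> NBSResult:
    """Network-based-statistic FWER correction over edges.

    ``features`` is subjects x edges; ``labels`` is +1/-1.  The primary
    threshold is the two-sided |t| quantile at ``primary_p``; component
    p-values are the fraction of label permutations whose maximal
    suprathreshold component is at least as large (in edges) as the
    observed component.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    labels = np.asarray(labels, dtype=int)
    features = np.asarray(features, dtype=float)
    if features.shape[1] != edges.n_edges:
        raise ValueError("feature count does not match edge index")
    pat, con = labels == 1, labels == -1
    if pat.sum() < 2 or con.sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    df = len(labels) - 2
    t_crit = stats.t.ppf(1.0 - primary_p / 2.0, df)

    def supra_mask(lab_pat: np.ndarray) -> np.ndarray:
        t, degen = pooled_tstats(features[lab_pat], features[~lab_pat])
        m = np.zeros(features.shape[1], dtype=bool)
        ok = ~degen
        m[ok] = np.abs(t[ok]) >= t_crit
        return m

    comps, sizes = _components_above(supra_mask(pat), edges)

    rng = np.random.default_rng(seed)
    n = len(labels)
    n_pat = int(pat.sum())
    null_max = np.zeros(n_perm)
    for b in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_pat, replace=False)] = True
        if perm.all() or not perm.any():
            raise ValueError("degenerate permutation: one group empty")
        _, psizes = _components_above(supra_mask(perm), edges)
        null_max[b] = psizes[0] if len(psizes) else 0
    pvals = np.array([float(np.mean(null_max >= s)) for s in sizes])
    return NBSResult(
        primary_threshold=float(t_crit),
        components=comps,
        component_sizes=sizes,
        component_pvalues=pvals,
        n_permutations=n_perm,
        seed=seed,
        alpha_fwer=alpha_fwer,
    )
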