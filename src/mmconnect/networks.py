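"""Individual brain-network construction for the three modalities.

* Morphological: per-ROI grey-matter value distributions are estimated by
  Gaussian kernel density estimation on a shared grid of ``n_points``
  (default 2**7 = 128) points, converted to probability mass vectors, and
  compared pairwise with the symmetrised Kullback-Leibler divergence

      D_KL(P, Q) = sum_i [ P(i) ln(P(i)/Q(i)) + Q(i) ln(Q(i)/P(i)) ]

  The edge weight is the KL-based similarity KLS(P, Q) = exp(-D_KL),
  which lies in (0, 1] and equals 1 iff the two distributions coincide
  on the grid.

* Structural: directed tractography probabilities p(i->j) =
  counts[i,j] / (samples_per_voxel * n_voxels(i)) are symmetrised by
  averaging, P_ij = (p(i->j) + p(j->i)) / 2.

* Functional: pairwise Pearson correlation of ROI time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .netio import ConnectivityMatrix, DataError, Modality, Parcellation
from .synthetic import RegionSamples, RoiTimeSeries, TractographyCounts

__all__ = [
    "DensityEstimate",
    "KLResult",
    "DegenerateDistributionError",
    "IncompatibleDensityError",
    "estimate_density",
    "symmetric_kl",
    "build_morphological_network",
    "build_structural_network",
    "build_functional_network",
]

N_POINTS_DEFAULT = 128  # 2**7 grid points
MASS_FLOOR = 1e-10  # floor before logs; KL undefined at exact zeros


class DegenerateDistributionError(ValueError):
    """Zero-variance input: no density can be estimated."""


class IncompatibleDensityError(ValueError):
    """Two densities on different grids cannot be compared."""


@dataclass(frozen=True)
class DensityEstimate:
    """Discretised probability mass of one ROI's value distribution."""

    grid: np.ndarray
    mass: np.ndarray
    source_roi: int = -1

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.mass):
            raise ValueError("grid and mass lengths differ")
        if abs(float(self.mass.sum()) - 1.0) > 1e-9:
            raise ValueError("mass does not sum to 1")
        if (self.mass <= 0).any():
            raise ValueError("mass has non-positive entries after flooring")


@dataclass(frozen=True)
class KLResult:
    """Symmetric KL divergence (nats) and the derived similarity."""

    d_kl: float
    kls: float


def estimate_density(
    values: np.ndarray,
    n_points: int = N_POINTS_DEFAULT,
    grid_lo: float | None = None,
    grid_hi: float | None = None,
    source_roi: int = -1,
) -> DensityEstimate:
    """Gaussian-KDE probability mass on an equally spaced grid.

    Bandwidth follows Silverman's rule.  The evaluated density is
    renormalised to a mass vector, floored at 1e-10 and renormalised
    again so downstream KL terms are always finite.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 10:
        raise DataError("need at least 10 finite values for density estimation")
    if n_points < 8:
        raise ValueError(f"n_points must be >= 8, got {n_points}")
    if values.std() <= 1e-12 * max(1.0, float(np.abs(values).max())):
        raise DegenerateDistributionError("zero-variance sample")
    lo = float(values.min()) if grid_lo is None else float(grid_lo)
    hi = float(values.max()) if grid_hi is None else float(grid_hi)
    if not lo < hi:
        raise ValueError(f"grid_lo ({lo}) must be < grid_hi ({hi})")
    grid = np.linspace(lo, hi, n_points)
    kde = gaussian_kde(values, bw_method="silverman")
    dens = kde(grid)
    mass = dens / dens.sum() if dens.sum() > 0 else np.full(n_points, 1.0 / n_points)
    mass = np.maximum(mass, MASS_FLOOR)
    mass = mass / mass.sum()
    return DensityEstimate(grid=grid, mass=mass, source_roi=source_roi)


def symmetric_kl(p: DensityEstimate, q: DensityEstimate) -> KLResult:
    """Symmetrised KL divergence between two densities on the same grid."""
    if len(p.grid) != len(q.grid) or not np.allclose(p.grid, q.grid, rtol=0, atol=1e-12):
        raise IncompatibleDensityError("densities evaluated on different grids")
    pm, qm = p.mass, q.mass
    d = float(np.sum(pm * np.log(pm / qm) + qm * np.log(qm / pm)))
    d = max(d, 0.0)  # guard tiny negative rounding
    return KLResult(d_kl=d, kls=float(np.exp(-d)))


def build_morphological_network(
    s: RegionSamples,
    parcellation: Parcellation,
    n_points: int = N_POINTS_DEFAULT,
) -> ConnectivityMatrix:
    """KLS similarity matrix over all ROI pairs of one subject.

    All densities are evaluated on one shared grid spanning the union
    range of the subject's values, so every pairwise comparison uses
    common sample points.
    """
    n = parcellation.n_rois
    if set(s.samples) != set(range(n)):
        raise DataError("region samples do not cover the parcellation")
    all_vals = np.concatenate([s.samples[r] for r in range(n)])
    lo, hi = float(all_vals.min()), float(all_vals.max())
    if lo == hi:
        raise DegenerateDistributionError("all grey-matter values identical")
    masses = np.empty((n, n_points))
    for r in range(n):
        try:
            masses[r] = estimate_density(
                s.samples[r], n_points=n_points, grid_lo=lo, grid_hi=hi, source_roi=r
            ).mass
        except DegenerateDistributionError as exc:
            raise DegenerateDistributionError(f"ROI {r}: {exc}") from exc
    # D[i,j] = sum_k m_i ln m_i - m_i ln m_j + m_j ln m_j - m_j ln m_i
    logm = np.log(masses)
    ent = np.sum(masses * logm, axis=1)
    cross = masses @ logm.T
    d = ent[:, None] + ent[None, :] - cross - cross.T
    d = np.maximum((d + d.T) / 2.0, 0.0)
    kls = np.exp(-d)
    np.fill_diagonal(kls, 1.0)
    return ConnectivityMatrix(
        values=kls, modality=Modality.MORPHOLOGICAL, parcellation=parcellation
    )


def build_structural_network(
    t: TractographyCounts, parcellation: Parcellation
) -> ConnectivityMatrix:
    """Averaged non-directional connection probabilities P_ij."""
    counts = np.asarray(t.counts, dtype=float)
    totals = float(t.samples_per_voxel) * np.asarray(t.voxel_counts, dtype=float)
    if (totals <= 0).any():
        raise DataError("non-positive total sample count for a seed region")
    p_dir = counts / totals[:, None]
    if (p_dir > 1.0).any():
        raise DataError("fibre counts exceed samples seeded from region")
    p = (p_dir + p_dir.T) / 2.0
    np.fill_diagonal(p, 0.0)
    return ConnectivityMatrix(
        values=p, modality=Modality.STRUCTURAL, parcellation=parcellation
    )


def build_functional_network(
    ts: RoiTimeSeries, parcellation: Parcellation
) -> ConnectivityMatrix:
    """Pearson correlation matrix of the ROI time series."""
    v = np.asarray(ts.values, dtype=float)
    if v.shape[1] < 3:
        raise DataError("need at least 3 time points for correlation")
    if (v.std(axis=1) <= 1e-12 * max(1.0, float(np.abs(v).max()))).any():
        raise DegenerateDistributionError("constant ROI time series")
    r = np.corrcoef(v)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        values=r, modality=Modality.FUNCTIONAL, parcellation=parcellation
    )
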