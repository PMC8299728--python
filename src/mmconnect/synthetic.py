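"""Synthetic two-group multimodal cohorts with known discriminative edges.

The generator emulates the three post-preprocessing inputs the pipeline
consumes, at the level of a small clinical study (default 22 patients vs
20 controls):

* **morphological** — per-ROI grey-matter voxel values, drawn from
  per-ROI truncated normals on (0, 1]; patient ROIs listed in
  ``effect_rois`` get a mean shift, which perturbs the KL-similarity of
  every edge incident to them;
* **structural** — directed fibre-sample counts from probabilistic
  tractography, Binomial(samples_per_voxel x n_voxels, p_ij) with sparse,
  ring-distance-decaying base probabilities (short-range bias); patient
  probabilities on structural ``effect_edges`` are scaled by (1 + delta);
* **functional** — ROI x time BOLD-like series from a zero-mean
  multivariate normal with block-structured target correlations
  (within-block ~0.4, between ~0.05) plus per-subject jitter; patient
  target correlations on functional ``effect_edges`` are shifted by
  delta, followed by a nearest-positive-definite repair.

One master seed fans out into per-subject, per-modality substreams, so
any modality of any subject can be regenerated independently.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .netio import (
    DataError,
    Parcellation,
    write_manifest,
    write_region_samples,
    write_timeseries,
    write_tract_counts,
)

__all__ = [
    "SyntheticConfig",
    "RegionSamples",
    "TractographyCounts",
    "RoiTimeSeries",
    "ConfigError",
    "gen_region_samples",
    "gen_tractography_counts",
    "gen_timeseries",
    "gen_subject",
    "gen_cohort",
    "nearest_correlation",
]

# substream codes for seed fan-out
_STAGE_ROI_MEANS = 1
_STAGE_VOXELS = 2
_STAGE_MORPH = 3
_STAGE_STRUCT = 4
_STAGE_FUNC = 5


class ConfigError(ValueError):
    """Synthetic configuration that cannot produce valid data."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    ``effect_edges`` entries are (i, j, modality, delta) on 0-based ROI
    indices; ``effect_rois`` entries are (roi, mean_shift) applied to the
    patient group's grey-matter mean of that ROI.
    """

    n_rois: int = 246
    n_patients: int = 22
    n_controls: int = 20
    t_points: int = 230
    voxels_per_roi: tuple[int, int] = (50, 400)
    samples_per_voxel: int = 5000
    effect_edges: tuple[tuple[int, int, str, float], ...] = ()
    effect_rois: tuple[tuple[int, float], ...] = ()
    noise_sd: float = 0.1
    seed: int = 0
    # base morphology / connectivity shape parameters
    gm_mean_range: tuple[float, float] = (0.3, 0.7)
    struct_p0: float = 0.15
    struct_decay: float = 2.0
    block_size: int = 5
    within_block_r: float = 0.4
    between_block_r: float = 0.05
    subject_corr_jitter: float = 0.02

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ConfigError("n_rois must be >= 2")
        if self.n_patients < 2 or self.n_controls < 2:
            raise ConfigError("each group needs >= 2 subjects")
        if self.t_points < 10:
            raise ConfigError("t_points must be >= 10")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        for i, j, mod, _ in self.effect_edges:
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois and i != j):
                raise ConfigError(f"effect edge ({i},{j}) outside parcellation")
            if mod not in {"morphological", "structural", "functional"}:
                raise ConfigError(f"unknown effect modality {mod!r}")
        for r, _ in self.effect_rois:
            if not 0 <= r < self.n_rois:
                raise ConfigError(f"effect ROI {r} outside parcellation")

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    def parcellation(self) -> Parcellation:
        return Parcellation.generic(self.n_rois)


@dataclass
class RegionSamples:
    """Per-ROI grey-matter voxel values for one subject (values in (0,1])."""

    samples: dict[int, np.ndarray]  # 0-based ROI -> voxel values
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        for roi, v in self.samples.items():
            if len(v) < 10:
                raise DataError(f"ROI {roi}: fewer than 10 voxel values")
            if not np.isfinite(v).all() or (v <= 0).any() or (v > 1).any():
                raise DataError(f"ROI {roi}: values outside (0, 1]")


@dataclass
class TractographyCounts:
    """Directed fibre-sample counts; counts[i, j] = samples seeded in i hitting j."""

    counts: np.ndarray
    voxel_counts: np.ndarray
    samples_per_voxel: int
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        totals = self.samples_per_voxel * np.asarray(self.voxel_counts)[:, None]
        if (self.counts > totals).any():
            raise DataError("fibre counts exceed total samples seeded in region")
        if (self.counts < 0).any():
            raise DataError("negative fibre counts")


@dataclass
class RoiTimeSeries:
    """ROI x time matrix of BOLD-like signals for one subject."""

    values: np.ndarray
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all():
            raise DataError("non-finite time-series values")
        scale = max(1.0, float(np.abs(v).max()))
        if (v.std(axis=1) <= 1e-12 * scale).any():
            raise DataError("constant ROI time series")
        self.values = v


def _rng(cfg: SyntheticConfig, *key: int) -> np.random.Generator:
    """Deterministic substream keyed by (seed, *key)."""
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), *map(int, key)]))


def roi_means(cfg: SyntheticConfig) -> np.ndarray:
    """Per-ROI grey-matter means, fixed by the master seed."""
    lo, hi = cfg.gm_mean_range
    return _rng(cfg, _STAGE_ROI_MEANS).uniform(lo, hi, size=cfg.n_rois)


def roi_voxel_counts(cfg: SyntheticConfig) -> np.ndarray:
    """Per-ROI voxel counts, shared across subjects, fixed by the seed."""
    lo, hi = cfg.voxels_per_roi
    return _rng(cfg, _STAGE_VOXELS).integers(lo, hi + 1, size=cfg.n_rois)


def gen_region_samples(
    cfg: SyntheticConfig, subject_index: int, group: str
) -> RegionSamples:
    """Draw grey-matter voxel values for one subject.

    Values for ROI r come from Normal(mu_r, noise_sd) truncated to (0, 1];
    patients get mu_r shifted by each (r, mean_shift) in ``effect_rois``.
    """
    rng = _rng(cfg, _STAGE_MORPH, subject_index)
    mus = roi_means(cfg).copy()
    if group == "patient":
        for r, shift in cfg.effect_rois:
            mus[r] += shift
    n_vox = roi_voxel_counts(cfg)
    sd = cfg.noise_sd
    eps = 1e-12
    samples: dict[int, np.ndarray] = {}
    for r in range(cfg.n_rois):
        a, b = (eps - mus[r]) / sd, (1.0 - mus[r]) / sd
        if b <= a or stats.norm.cdf(b) - stats.norm.cdf(a) < 1e-12:
            raise ConfigError(
                f"ROI {r}: truncation to (0,1] leaves no support (mu={mus[r]:.3f})"
            )
        samples[r] = stats.truncnorm.rvs(
            a, b, loc=mus[r], scale=sd, size=int(n_vox[r]), random_state=rng
        )
    return RegionSamples(samples=samples, subject_id=f"sub{subject_index:03d}", group=group)


def base_connection_probabilities(cfg: SyntheticConfig) -> np.ndarray:
    """Sparse, ring-distance-decaying fibre connection probabilities."""
    n = cfg.n_rois
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    d = np.minimum(np.abs(i - j), n - np.abs(i - j))
    p = cfg.struct_p0 * np.exp(-d / cfg.struct_decay)
    p[d > max(2, n // 4)] = 0.0  # long-range pairs unconnected
    np.fill_diagonal(p, 0.0)
    return p


def gen_tractography_counts(
    cfg: SyntheticConfig, subject_index: int, group: str
) -> TractographyCounts:
    """Binomial fibre-sample counts for one subject."""
    rng = _rng(cfg, _STAGE_STRUCT, subject_index)
    p = base_connection_probabilities(cfg)
    if group == "patient":
        for i, j, mod, delta in cfg.effect_edges:
            if mod == "structural":
                p[i, j] *= 1.0 + delta
                p[j, i] *= 1.0 + delta
    if (p < 0).any() or (p > 1).any():
        raise ConfigError("structural effect pushes a connection probability outside [0,1]")
    n_vox = roi_voxel_counts(cfg)
    totals = cfg.samples_per_voxel * n_vox  # per seed region
    counts = rng.binomial(totals[:, None], p)
    np.fill_diagonal(counts, 0)
    return TractographyCounts(
        counts=counts,
        voxel_counts=n_vox,
        samples_per_voxel=cfg.samples_per_voxel,
        subject_id=f"sub{subject_index:03d}",
        group=group,
    )


def nearest_correlation(a: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Nearest-positive-definite repair: clip eigenvalues, restore unit diagonal."""
    a = (a + a.T) / 2.0
    w, v = np.linalg.eigh(a)
    w = np.clip(w, eig_floor, None)
    a = (v * w) @ v.T
    d = np.sqrt(np.diag(a))
    a = a / np.outer(d, d)
    np.fill_diagonal(a, 1.0)
    return (a + a.T) / 2.0


def target_correlation(cfg: SyntheticConfig, group: str) -> np.ndarray:
    """Block-structured target correlation, group effects applied, PD-repaired."""
    n = cfg.n_rois
    block = np.arange(n) // cfg.block_size
    same = block[:, None] == block[None, :]
    c = np.where(same, cfg.within_block_r, cfg.between_block_r)
    np.fill_diagonal(c, 1.0)
    if group == "patient":
        for i, j, mod, delta in cfg.effect_edges:
            if mod == "functional":
                c[i, j] += delta
                c[j, i] += delta
    c = np.clip(c - np.eye(n) * 0.0, -0.99, 0.99)
    np.fill_diagonal(c, 1.0)
    return nearest_correlation(c)


def gen_timeseries(cfg: SyntheticConfig, subject_index: int, group: str) -> RoiTimeSeries:
    """Multivariate-normal BOLD-like ROI time series for one subject."""
    rng = _rng(cfg, _STAGE_FUNC, subject_index)
    c = target_correlation(cfg, group)
    if cfg.subject_corr_jitter > 0:
        n = cfg.n_rois
        jit = rng.normal(0.0, cfg.subject_corr_jitter, size=(n, n))
        jit = (jit + jit.T) / 2.0
        np.fill_diagonal(jit, 0.0)
        c = nearest_correlation(c + jit)
    chol = np.linalg.cholesky(c)
    z = rng.standard_normal((cfg.n_rois, cfg.t_points))
    ts = chol @ z
    return RoiTimeSeries(values=ts, subject_id=f"sub{subject_index:03d}", group=group)


def gen_subject(
    cfg: SyntheticConfig, subject_index: int, group: str
) -> tuple[RegionSamples, TractographyCounts, RoiTimeSeries]:
    """All three raw modality inputs for one subject."""
    return (
        gen_region_samples(cfg, subject_index, group),
        gen_tractography_counts(cfg, subject_index, group),
        gen_timeseries(cfg, subject_index, group),
    )


def subject_groups(cfg: SyntheticConfig) -> list[str]:
    """Group assignment by subject index: patients first, then controls."""
    return ["patient"] * cfg.n_patients + ["control"] * cfg.n_controls


def gen_cohort(cfg: SyntheticConfig, out_dir: str | os.PathLike) -> str:
    """Write a full cohort (manifest, parcellation, raw inputs, ground truth).

    Returns the manifest path.  Layout::

        out_dir/manifest.tsv
        out_dir/parcellation.tsv
        out_dir/effects.tsv          # injected ground truth, for scoring
        out_dir/subjects/<id>_{morph,counts,voxels,func}.tsv
    """
    out_dir = os.fspath(out_dir)
    sub_dir = os.path.join(out_dir, "subjects")
    os.makedirs(sub_dir, exist_ok=True)
    parc = cfg.parcellation()

    import pandas as pd

    pd.DataFrame(
        {"label_id": parc.label_ids, "name": parc.names}
    ).to_csv(os.path.join(out_dir, "parcellation.tsv"), sep="\t", index=False)

    truth_rows = [
        {"kind": "edge", "i": i, "j": j, "modality": mod, "delta": delta}
        for i, j, mod, delta in cfg.effect_edges
    ] + [
        {"kind": "roi", "i": r, "j": -1, "modality": "morphological", "delta": shift}
        for r, shift in cfg.effect_rois
    ]
    pd.DataFrame(truth_rows, columns=["kind", "i", "j", "modality", "delta"]).to_csv(
        os.path.join(out_dir, "effects.tsv"), sep="\t", index=False
    )

    rows = []
    for k, group in enumerate(subject_groups(cfg)):
        rs, tc, ts = gen_subject(cfg, k, group)
        sid = rs.subject_id
        paths = {
            "morph_path": os.path.join("subjects", f"{sid}_morph.tsv"),
            "struct_counts_path": os.path.join("subjects", f"{sid}_counts.tsv"),
            "struct_voxels_path": os.path.join("subjects", f"{sid}_voxels.tsv"),
            "func_path": os.path.join("subjects", f"{sid}_func.tsv"),
        }
        write_region_samples(
            {int(parc.label_ids[r]): v for r, v in rs.samples.items()},
            os.path.join(out_dir, paths["morph_path"]),
        )
        write_tract_counts(
            tc.counts,
            tc.voxel_counts,
            tc.samples_per_voxel,
            parc,
            os.path.join(out_dir, paths["struct_counts_path"]),
            os.path.join(out_dir, paths["struct_voxels_path"]),
        )
        write_timeseries(ts.values, parc, os.path.join(out_dir, paths["func_path"]))
        rows.append({"subject_id": sid, "group": group, **paths})
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    write_manifest(rows, manifest_path)
    return manifest_path


def with_seed(cfg: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Same study conditions under a different master seed."""
    return replace(cfg, seed=int(seed))
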