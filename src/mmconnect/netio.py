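"""Parcellations, connectivity matrices, edge indexing and file formats.

Everything downstream works on a single in-memory contract:

* a :class:`Parcellation` names the network nodes (atlas regions of
  interest, ROIs).  Internally ROIs are 0-based positions; every file and
  report uses the atlas ``label_id`` (1-based by convention).
* a :class:`ConnectivityMatrix` is one subject's (or one group's) weighted
  network for one modality, with the modality fixing the diagonal
  convention and admissible value range.
* an :class:`EdgeIndex` is the canonical bijection between the upper
  triangle of an N x N matrix and a flat feature vector of length
  N(N-1)/2, ordered lexicographically by (i, j) with i < j.

File dialects are deliberately plain: tab-separated square matrices with
label_id headers, tab-separated edge lists, and a one-row-per-subject
cohort manifest.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "Parcellation",
    "EdgeIndex",
    "ConnectivityMatrix",
    "CohortDataset",
    "ParcellationError",
    "AsymmetryError",
    "FormatError",
    "DataError",
    "edge_index",
    "vectorize",
    "devectorize",
    "read_matrix",
    "write_matrix",
    "read_edge_list",
    "write_edge_list",
    "read_manifest",
    "write_manifest",
    "read_region_samples",
    "write_region_samples",
    "read_timeseries",
    "write_timeseries",
    "read_tract_counts",
    "write_tract_counts",
]

SYMMETRY_TOL = 1e-12  # construction-time symmetry requirement
FILE_TOL = 1e-9  # round-trip tolerance for text formats


class ParcellationError(ValueError):
    """Invalid parcellation (too few ROIs, duplicate labels ...)."""


class AsymmetryError(ValueError):
    """A matrix that should be symmetric is not, beyond tolerance."""


class FormatError(ValueError):
    """A file's layout does not match the expected dialect/parcellation."""


class DataError(ValueError):
    """A file parsed but carries invalid values (NaN, counts overflow ...)."""


class Modality(str, enum.Enum):
    """Imaging modality of a network; fixes diagonal and value range."""

    MORPHOLOGICAL = "morphological"
    STRUCTURAL = "structural"
    FUNCTIONAL = "functional"

    @property
    def diagonal(self) -> float:
        # self-similarity 1 (KLS, Pearson); self connection probability 0
        return 0.0 if self is Modality.STRUCTURAL else 1.0

    @property
    def value_range(self) -> tuple[float, float]:
        return (-1.0, 1.0) if self is Modality.FUNCTIONAL else (0.0, 1.0)


@dataclass(frozen=True)
class Parcellation:
    """An atlas parcellation: ordered (label_id, name) pairs."""

    labels: tuple[tuple[int, str], ...]
    atlas_name: str = "custom"

    def __post_init__(self) -> None:
        ids = [lid for lid, _ in self.labels]
        if len(ids) < 2:
            raise ParcellationError("a parcellation needs at least 2 ROIs")
        if len(set(ids)) != len(ids):
            raise ParcellationError("duplicate label_ids in parcellation")
        if ids != sorted(ids):
            raise ParcellationError("label_ids must be sorted ascending")
        if any(lid < 1 for lid in ids):
            raise ParcellationError("label_ids must be >= 1")

    @property
    def n_rois(self) -> int:
        return len(self.labels)

    @property
    def label_ids(self) -> np.ndarray:
        return np.array([lid for lid, _ in self.labels], dtype=int)

    @property
    def names(self) -> list[str]:
        return [name for _, name in self.labels]

    @classmethod
    def generic(cls, n_rois: int, atlas_name: str | None = None) -> "Parcellation":
        """Auto-named parcellation ROI1..ROIn with label_ids 1..n."""
        if n_rois < 2:
            raise ParcellationError(f"n_rois must be >= 2, got {n_rois}")
        labels = tuple((k, f"ROI{k}") for k in range(1, n_rois + 1))
        return cls(labels=labels, atlas_name=atlas_name or f"generic{n_rois}")

    @classmethod
    def bn246(cls) -> "Parcellation":
        """246-region whole-brain parcellation (Brainnetome-style)."""
        return cls.generic(246, "BN246")

    @classmethod
    def aal90(cls) -> "Parcellation":
        """90-region whole-brain parcellation (AAL-style)."""
        return cls.generic(90, "AAL90")


@dataclass(frozen=True)
class EdgeIndex:
    """Bijection between upper-triangle entries and a flat edge vector."""

    n_rois: int
    rows: np.ndarray = field(repr=False)
    cols: np.ndarray = field(repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.rows)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.rows.tolist(), self.cols.tolist()))


def edge_index(n_rois: int) -> EdgeIndex:
    """All unordered ROI pairs i<j in lexicographic order.

    For a 246-ROI parcellation this yields the 30,135 = 246*245/2 unique
    network edges.
    """
    if n_rois < 2:
        raise ParcellationError(f"n_rois must be >= 2, got {n_rois}")
    rows, cols = np.triu_indices(n_rois, k=1)
    return EdgeIndex(n_rois=n_rois, rows=rows, cols=cols)


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted network for one subject/group and one modality."""

    values: np.ndarray
    modality: Modality
    parcellation: Parcellation

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = self.parcellation.n_rois
        if v.shape != (n, n):
            raise FormatError(
                f"matrix shape {v.shape} does not match parcellation of {n} ROIs"
            )
        if not np.isfinite(v).all():
            raise DataError("connectivity matrix contains non-finite entries")
        if np.max(np.abs(v - v.T)) > max(SYMMETRY_TOL, 1e-12 * max(1.0, np.abs(v).max())):
            raise AsymmetryError("connectivity matrix is not symmetric")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, self.modality.diagonal)
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.parcellation.n_rois


def vectorize(m: ConnectivityMatrix) -> np.ndarray:
    """Upper-triangle edge vector in :func:`edge_index` order."""
    idx = edge_index(m.n_rois)
    return m.values[idx.rows, idx.cols].copy()


def devectorize(
    v: np.ndarray, parcellation: Parcellation, modality: Modality
) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize`; diagonal restored from the modality."""
    v = np.asarray(v, dtype=float)
    n = parcellation.n_rois
    idx = edge_index(n)
    if v.shape != (idx.n_edges,):
        raise FormatError(
            f"edge vector length {v.shape} does not match {idx.n_edges} edges"
        )
    out = np.zeros((n, n))
    out[idx.rows, idx.cols] = v
    out = out + out.T
    np.fill_diagonal(out, modality.diagonal)
    return ConnectivityMatrix(values=out, modality=modality, parcellation=parcellation)


@dataclass
class CohortDataset:
    """Edge-feature tables for each modality over a shared subject order.

    ``labels`` codes patients as +1 and controls as -1.
    """

    features: dict[str, np.ndarray]  # modality name -> (n_subjects, n_edges)
    labels: np.ndarray
    subject_ids: list[str]
    parcellation: Parcellation

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.subject_ids)
        if set(np.unique(self.labels)) - {1, -1}:
            raise DataError("labels must be +1 (patient) / -1 (control)")
        if 1 not in self.labels or -1 not in self.labels:
            raise DataError("both classes must be present")
        n_edges = edge_index(self.parcellation.n_rois).n_edges
        for mod, X in self.features.items():
            if X.shape != (n, n_edges):
                raise FormatError(
                    f"{mod} feature table has shape {X.shape}, "
                    f"expected ({n}, {n_edges})"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


# ---------------------------------------------------------------------------
# square-matrix TSV dialect

def write_matrix(m: ConnectivityMatrix, path: str | os.PathLike) -> None:
    ids = m.parcellation.label_ids
    df = pd.DataFrame(m.values, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_matrix(
    path: str | os.PathLike, parcellation: Parcellation, modality: Modality
) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = parcellation.label_ids
    if df.shape != (len(ids), len(ids)):
        raise FormatError(
            f"{path}: matrix is {df.shape}, parcellation has {len(ids)} ROIs"
        )
    try:
        file_ids = df.columns.astype(int).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-integer column headers") from exc
    if not np.array_equal(file_ids, ids) or not np.array_equal(
        df.index.to_numpy().astype(int), ids
    ):
        raise FormatError(f"{path}: label_id headers do not match parcellation")
    v = df.to_numpy(dtype=float)
    if np.isnan(v).any():
        raise DataError(f"{path}: NaN entries in matrix")
    if np.max(np.abs(v - v.T)) > 1e-8:
        raise AsymmetryError(f"{path}: matrix asymmetric beyond file tolerance")
    v = (v + v.T) / 2.0
    return ConnectivityMatrix(values=v, modality=modality, parcellation=parcellation)


# ---------------------------------------------------------------------------
# edge-list TSV dialect (label_i, name_i, label_j, name_j, value)

def write_edge_list(m: ConnectivityMatrix, path: str | os.PathLike) -> None:
    idx = edge_index(m.n_rois)
    ids = m.parcellation.label_ids
    names = m.parcellation.names
    df = pd.DataFrame(
        {
            "label_i": ids[idx.rows],
            "name_i": [names[i] for i in idx.rows],
            "label_j": ids[idx.cols],
            "name_j": [names[j] for j in idx.cols],
            "value": m.values[idx.rows, idx.cols],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_edge_list(
    path: str | os.PathLike, parcellation: Parcellation, modality: Modality
) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t")
    idx = edge_index(parcellation.n_rois)
    if len(df) != idx.n_edges:
        raise FormatError(
            f"{path}: {len(df)} edge rows, expected {idx.n_edges}"
        )
    if df["value"].isna().any():
        raise DataError(f"{path}: NaN edge values")
    pos = {lid: k for k, lid in enumerate(parcellation.label_ids.tolist())}
    vec = np.full(idx.n_edges, np.nan)
    flat = {(i, j): k for k, (i, j) in enumerate(idx.pairs)}
    for li, lj, val in zip(df["label_i"], df["label_j"], df["value"]):
        if li not in pos or lj not in pos:
            raise FormatError(f"{path}: label_id outside parcellation")
        i, j = sorted((pos[li], pos[lj]))
        vec[flat[(i, j)]] = val
    if np.isnan(vec).any():
        raise FormatError(f"{path}: edge list does not cover every ROI pair")
    return devectorize(vec, parcellation, modality)


# ---------------------------------------------------------------------------
# raw per-subject inputs

def write_region_samples(samples: dict[int, np.ndarray], path: str | os.PathLike) -> None:
    """Grey-matter voxel values per ROI: long TSV (label_id, value)."""
    lids, vals = [], []
    for lid in sorted(samples):
        v = np.asarray(samples[lid], dtype=float)
        lids.extend([lid] * len(v))
        vals.extend(v.tolist())
    pd.DataFrame({"label_id": lids, "value": vals}).to_csv(
        path, sep="\t", index=False, float_format="%.9g"
    )


def read_region_samples(path: str | os.PathLike) -> dict[int, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if df["value"].isna().any():
        raise DataError(f"{path}: NaN grey-matter values")
    return {
        int(lid): grp["value"].to_numpy(dtype=float)
        for lid, grp in df.groupby("label_id", sort=True)
    }


def write_timeseries(ts: np.ndarray, parcellation: Parcellation, path: str | os.PathLike) -> None:
    """ROI x time matrix, rows indexed by label_id."""
    df = pd.DataFrame(ts, index=parcellation.label_ids)
    df.to_csv(path, sep="\t", float_format="%.9g")


def read_timeseries(path: str | os.PathLike, parcellation: Parcellation) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not np.array_equal(df.index.to_numpy().astype(int), parcellation.label_ids):
        raise FormatError(f"{path}: row labels do not match parcellation")
    v = df.to_numpy(dtype=float)
    if np.isnan(v).any():
        raise DataError(f"{path}: NaN time-series values")
    return v


def write_tract_counts(
    counts: np.ndarray,
    voxel_counts: np.ndarray,
    samples_per_voxel: int,
    parcellation: Parcellation,
    counts_path: str | os.PathLike,
    voxels_path: str | os.PathLike,
) -> None:
    ids = parcellation.label_ids
    pd.DataFrame(counts.astype(int), index=ids, columns=ids).to_csv(
        counts_path, sep="\t"
    )
    pd.DataFrame(
        {
            "label_id": ids,
            "n_voxels": np.asarray(voxel_counts, dtype=int),
            "samples_per_voxel": samples_per_voxel,
        }
    ).to_csv(voxels_path, sep="\t", index=False)


def read_tract_counts(
    counts_path: str | os.PathLike,
    voxels_path: str | os.PathLike,
    parcellation: Parcellation,
) -> tuple[np.ndarray, np.ndarray, int]:
    ids = parcellation.label_ids
    cdf = pd.read_csv(counts_path, sep="\t", index_col=0)
    if not np.array_equal(cdf.columns.astype(int).to_numpy(), ids):
        raise FormatError(f"{counts_path}: headers do not match parcellation")
    counts = cdf.to_numpy(dtype=np.int64)
    if (counts < 0).any():
        raise DataError(f"{counts_path}: negative fibre counts")
    vdf = pd.read_csv(voxels_path, sep="\t")
    if not np.array_equal(vdf["label_id"].to_numpy(), ids):
        raise FormatError(f"{voxels_path}: label_ids do not match parcellation")
    voxels = vdf["n_voxels"].to_numpy(dtype=np.int64)
    if (voxels <= 0).any():
        raise DataError(f"{voxels_path}: non-positive voxel counts")
    spv = int(vdf["samples_per_voxel"].iloc[0])
    return counts, voxels, spv


# ---------------------------------------------------------------------------
# cohort manifest: one row per subject

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "morph_path",
    "struct_counts_path",
    "struct_voxels_path",
    "func_path",
]


def write_manifest(rows: list[dict], path: str | os.PathLike) -> None:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def region_samples_from_nifti(
    label_volume_path: str | os.PathLike,
    value_volume_path: str | os.PathLike,
    parcellation: Parcellation,
) -> dict[int, np.ndarray]:
    """Extract per-ROI voxel values from an atlas label volume.

    Requires ``nibabel`` (optional dependency).  Returns a mapping
    label_id -> grey-matter values of the voxels carrying that label.
    """
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError(
            "NIfTI extraction requires the optional dependency nibabel"
        ) from exc
    labels = np.asarray(nib.load(os.fspath(label_volume_path)).dataobj).round().astype(int)
    values = np.asarray(nib.load(os.fspath(value_volume_path)).dataobj, dtype=float)
    if labels.shape != values.shape:
        raise FormatError("label and value volumes have different shapes")
    out: dict[int, np.ndarray] = {}
    for lid in parcellation.label_ids.tolist():
        v = values[labels == lid]
        if v.size == 0:
            raise DataError(f"atlas label {lid} has no voxels in the volume")
        out[lid] = v
    return out


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    bad = set(df["group"].unique()) - {"patient", "control"}
    if bad:
        raise DataError(f"{path}: unknown group labels {sorted(bad)}")
    return df
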