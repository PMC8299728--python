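"""Consensus connections: edges selected in every cross-validation fold.

The consensus set of a modality is the intersection of the per-outer-fold
t-test selections recorded during nested LOOCV.  Each consensus edge is
annotated with full-sample group means, a full-sample two-sided t-test
p-value, and a sign: positive when the patient mean exceeds the control
mean (increased connectivity in patients), negative when it is lower.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netio import Parcellation, edge_index
from .selection import edge_ttest

__all__ = ["ConsensusReport", "consensus_edges", "annotate_consensus"]


@dataclass
class ConsensusReport:
    """Annotated consensus connections for one modality."""

    modality: str
    n_folds: int
    table: pd.DataFrame  # label_i, name_i, label_j, name_j, means, p, sign
    frequencies: np.ndarray  # per-edge selection frequency over folds

    @property
    def edge_rows(self) -> int:
        return len(self.table)


def consensus_edges(fold_masks: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Selection frequency per edge and the all-folds consensus mask."""
    if not fold_masks:
        raise ValueError("need at least one fold mask")
    stack = np.vstack([np.asarray(m, dtype=bool) for m in fold_masks])
    if stack.ndim != 2:
        raise ValueError("fold masks must share one edge count")
    freq = stack.sum(axis=0)
    return freq, freq == len(fold_masks)


def annotate_consensus(
    fold_masks: list[np.ndarray],
    features: np.ndarray,
    labels: np.ndarray,
    parcellation: Parcellation,
    modality: str,
) -> ConsensusReport:
    """Build the consensus-connection table for one modality.

    ``features`` is the full-sample subjects x edges table; the report is
    sorted by ascending full-sample p-value.
    """
    labels = np.asarray(labels, dtype=int)
    freq, cons = consensus_edges(fold_masks)
    idx = edge_index(parcellation.n_rois)
    if len(freq) != idx.n_edges:
        raise ValueError("fold masks do not match the parcellation's edge count")
    ids = parcellation.label_ids
    names = parcellation.names
    stats = edge_ttest(features[labels == 1], features[labels == -1], alpha=1.0)
    rows = []
    for e in np.flatnonzero(cons):
        i, j = int(idx.rows[e]), int(idx.cols[e])
        mp, mc = float(stats.mean_patient[e]), float(stats.mean_control[e])
        sign = "positive" if mp > mc else ("negative" if mp < mc else "none")
        rows.append(
            {
                "label_i": int(ids[i]),
                "name_i": names[i],
                "label_j": int(ids[j]),
                "name_j": names[j],
                "mean_patient": mp,
                "mean_control": mc,
                "p_value": float(stats.p[e]),
                "sign": sign,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "label_i",
            "name_i",
            "label_j",
            "name_j",
            "mean_patient",
            "mean_control",
            "p_value",
            "sign",
        ],
    )
    if len(table):
        table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    return ConsensusReport(
        modality=modality,
        n_folds=len(fold_masks),
        table=table,
        frequencies=freq,
    )


def write_brainnet_files(
    report: ConsensusReport,
    parcellation: Parcellation,
    node_path: str,
    edge_path: str,
    coordinates: np.ndarray | None = None,
) -> None:
    """Plain-text .node/.edge files for surface-viewer visualisation.

    Nodes carry (x, y, z, colour, size, name); without supplied MNI
    coordinates a unit-circle layout is used, which is sufficient for
    schematic plots.  Edge weights are +1/-1 by consensus sign.
    """
    n = parcellation.n_rois
    if coordinates is None:
        theta = 2 * np.pi * np.arange(n) / n
        coordinates = np.column_stack(
            [80 * np.cos(theta), 80 * np.sin(theta), np.zeros(n)]
        )
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (n, 3):
        raise ValueError("coordinates must be (n_rois, 3)")
    pos = {lid: k for k, lid in enumerate(parcellation.label_ids.tolist())}
    involved = np.zeros(n, dtype=int)
    w = np.zeros((n, n))
    for row in report.table.itertuples():
        i, j = pos[row.label_i], pos[row.label_j]
        involved[i] = involved[j] = 1
        w[i, j] = w[j, i] = 1.0 if row.sign == "positive" else -1.0
    with open(node_path, "w") as fh:
        for k, (lid, name) in enumerate(parcellation.labels):
            x, y, z = coordinates[k]
            fh.write(f"{x:.2f}\t{y:.2f}\t{z:.2f}\t{1 + involved[k]}\t"
                     f"{1 + involved[k]}\t{name}\n")
    with open(edge_path, "w") as fh:
        for k in range(n):
            fh.write("\t".join(f"{w[k, m]:g}" for m in range(n)) + "\n")
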