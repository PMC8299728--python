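"""Group-average networks, nodal strength, and top-5% hub identification.

Hubs follow the weighted-degree convention: nodal strength is the sum of
absolute edge weights incident to a node on the group-average network,
and the top floor(fraction * N) nodes by strength (ties broken towards
the smaller atlas label) are the hubs.  For a 246-ROI parcellation at
the default fraction 0.05 this yields 12 hubs per modality and group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netio import ConnectivityMatrix

__all__ = ["HubReport", "group_average", "nodal_strength", "identify_hubs"]


@dataclass(frozen=True)
class HubReport:
    """Strength-ranked nodes and the hub subset for one network."""

    modality: str
    group: str
    ranking: tuple[tuple[int, str, float], ...]  # (label_id, name, strength), desc
    hub_labels: tuple[int, ...]

    @property
    def n_hubs(self) -> int:
        return len(self.hub_labels)


def group_average(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of individual networks of one modality."""
    if not matrices:
        raise ValueError("need at least one matrix to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.modality is not first.modality:
            raise ValueError("cannot average networks of mixed modalities")
        if m.parcellation.n_rois != first.parcellation.n_rois:
            raise ValueError("cannot average networks over different parcellations")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(
        values=mean, modality=first.modality, parcellation=first.parcellation
    )


def nodal_strength(m: ConnectivityMatrix) -> np.ndarray:
    """Weighted degree: sum of absolute off-diagonal weights per node."""
    w = np.abs(m.values).copy()
    np.fill_diagonal(w, 0.0)
    return w.sum(axis=1)


def identify_hubs(
    m: ConnectivityMatrix, fraction: float = 0.05, group: str = ""
) -> HubReport:
    """Top floor(fraction * N) nodes by strength on the given network."""
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n = m.n_rois
    k = int(np.floor(fraction * n))
    if k == 0:
        raise ValueError(
            f"fraction {fraction} of {n} ROIs yields zero hubs; increase fraction"
        )
    strengths = nodal_strength(m)
    ids = m.parcellation.label_ids
    names = m.parcellation.names
    order = sorted(range(n), key=lambda i: (-strengths[i], ids[i]))
    ranking = tuple((int(ids[i]), names[i], float(strengths[i])) for i in order)
    hubs = tuple(int(ids[i]) for i in order[:k])
    return HubReport(
        modality=m.modality.value, group=group, ranking=ranking, hub_labels=hubs
    )
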