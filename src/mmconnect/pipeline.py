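"""End-to-end orchestration: simulate -> networks -> hubs -> select ->
classify -> consensus, with file-based stage outputs and provenance.

Every stage writes its artefacts into the run directory so stages are
independently re-runnable; a rerun with the same configuration and seed
reproduces every output (stochastic stages included, since all
randomness flows from the master seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import annotate_consensus
from .graph import group_average, identify_hubs
from .mksvm import nested_loocv
from .netio import (
    CohortDataset,
    ConnectivityMatrix,
    Parcellation,
    read_manifest,
    read_region_samples,
    read_timeseries,
    read_tract_counts,
    vectorize,
    write_matrix,
)
from .networks import (
    build_functional_network,
    build_morphological_network,
    build_structural_network,
)
from .selection import edge_ttest, nbs_correct
from .synthetic import (
    RegionSamples,
    RoiTimeSeries,
    SyntheticConfig,
    TractographyCounts,
    gen_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "load_cohort", "build_cohort_networks"]

MODALITIES = ("morphological", "structural", "functional")


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    out_dir: str = "run"
    n_rois: int = 246  # 246 or 90 for the named atlases; any >=6 accepted
    modalities: tuple[str, ...] = MODALITIES
    n_points: int = 128
    alpha: float = 0.01
    hub_fraction: float = 0.05
    run_nbs: bool = True
    n_perm: int = 1000
    c_exponents: tuple[int, int] = (-5, 5)
    beta_step: float = 0.1
    seed: int = 0
    simulate: bool = True  # generate a synthetic cohort if no manifest given
    manifest: str | None = None
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides

    def c_grid(self) -> np.ndarray:
        lo, hi = self.c_exponents
        return 2.0 ** np.arange(lo, hi + 1)

    def synthetic_config(self) -> SyntheticConfig:
        kwargs = dict(self.synthetic)
        for key in ("effect_edges", "effect_rois"):
            if key in kwargs:
                kwargs[key] = tuple(tuple(x) for x in kwargs[key])
        kwargs.setdefault("n_rois", self.n_rois)
        kwargs.setdefault("seed", self.seed)
        return SyntheticConfig(**kwargs)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("modalities", "c_exponents"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_cohort(
    manifest_path: str | os.PathLike,
    parcellation: Parcellation,
    n_points: int = 128,
    modalities: tuple[str, ...] = MODALITIES,
) -> CohortDataset:
    """Read raw per-subject inputs from a manifest and build all networks."""
    df = read_manifest(manifest_path)
    base = os.path.dirname(os.fspath(manifest_path))
    pos = {int(lid): k for k, lid in enumerate(parcellation.label_ids)}
    subjects = []
    for _, row in df.iterrows():
        raw = {}
        if "morphological" in modalities:
            labelled = read_region_samples(os.path.join(base, row["morph_path"]))
            raw["morphological"] = RegionSamples(
                samples={pos[lid]: v for lid, v in labelled.items()},
                subject_id=row["subject_id"],
                group=row["group"],
            )
        if "structural" in modalities:
            counts, voxels, spv = read_tract_counts(
                os.path.join(base, row["struct_counts_path"]),
                os.path.join(base, row["struct_voxels_path"]),
                parcellation,
            )
            raw["structural"] = TractographyCounts(
                counts=counts,
                voxel_counts=voxels,
                samples_per_voxel=spv,
                subject_id=row["subject_id"],
                group=row["group"],
            )
        if "functional" in modalities:
            raw["functional"] = RoiTimeSeries(
                values=read_timeseries(os.path.join(base, row["func_path"]), parcellation),
                subject_id=row["subject_id"],
                group=row["group"],
            )
        subjects.append((row["subject_id"], row["group"], raw))
    return build_cohort_networks(subjects, parcellation, n_points, modalities)


def build_cohort_networks(
    subjects: list[tuple[str, str, dict]],
    parcellation: Parcellation,
    n_points: int = 128,
    modalities: tuple[str, ...] = MODALITIES,
    matrices_out: str | None = None,
) -> CohortDataset:
    """Build per-subject networks and stack them into edge-feature tables."""
    feats: dict[str, list[np.ndarray]] = {m: [] for m in modalities}
    nets: dict[str, list[ConnectivityMatrix]] = {m: [] for m in modalities}
    labels, ids = [], []
    for sid, group, raw in subjects:
        try:
            for mod in modalities:
                if mod == "morphological":
                    net = build_morphological_network(
                        raw[mod], parcellation, n_points=n_points
                    )
                elif mod == "structural":
                    net = build_structural_network(raw[mod], parcellation)
                else:
                    net = build_functional_network(raw[mod], parcellation)
                feats[mod].append(vectorize(net))
                nets[mod].append(net)
        except Exception as exc:
            raise RuntimeError(f"network construction failed for {sid}: {exc}") from exc
        labels.append(1 if group == "patient" else -1)
        ids.append(sid)
    if matrices_out:
        os.makedirs(matrices_out, exist_ok=True)
        for mod in modalities:
            for sid, net in zip(ids, nets[mod]):
                write_matrix(net, os.path.join(matrices_out, f"{sid}_{mod}.tsv"))
    ds = CohortDataset(
        features={m: np.vstack(v) for m, v in feats.items()},
        labels=np.array(labels),
        subject_ids=ids,
        parcellation=parcellation,
    )
    ds._networks = nets  # stage handoff for hub analysis
    return ds


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the classification report dict."""
    t0 = time.time()
    os.makedirs(cfg.out_dir, exist_ok=True)
    timings: dict[str, float] = {}

    parcellation = Parcellation.generic(cfg.n_rois)

    # --- simulate / load ---------------------------------------------------
    t = time.time()
    if cfg.manifest is None:
        if not cfg.simulate:
            raise ValueError("no manifest given and simulation disabled")
        manifest = gen_cohort(cfg.synthetic_config(), os.path.join(cfg.out_dir, "cohort"))
    else:
        manifest = cfg.manifest
    timings["simulate"] = time.time() - t

    t = time.time()
    ds = load_cohort(manifest, parcellation, cfg.n_points, cfg.modalities)
    timings["networks"] = time.time() - t

    # --- hubs --------------------------------------------------------------
    t = time.time()
    hub_rows = []
    nets = ds._networks
    for mod in cfg.modalities:
        for group, want in (("patient", 1), ("control", -1)):
            mats = [m for m, y in zip(nets[mod], ds.labels) if y == want]
            avg = group_average(mats)
            rep = identify_hubs(avg, fraction=cfg.hub_fraction, group=group)
            for rank, lid in enumerate(rep.hub_labels, start=1):
                name = dict(zip(parcellation.label_ids, parcellation.names))[lid]
                hub_rows.append(
                    {"modality": mod, "group": group, "rank": rank,
                     "label_id": lid, "roi": name}
                )
    pd.DataFrame(hub_rows).to_csv(
        os.path.join(cfg.out_dir, "hubs.tsv"), sep="\t", index=False
    )
    timings["hubs"] = time.time() - t

    # --- full-sample selection + NBS ---------------------------------------
    t = time.time()
    from .netio import edge_index as _edge_index

    idx = _edge_index(cfg.n_rois)
    nbs_summary = {}
    for mod in cfg.modalities:
        X = ds.features[mod]
        st = edge_ttest(X[ds.labels == 1], X[ds.labels == -1], alpha=cfg.alpha)
        ids = parcellation.label_ids
        names = parcellation.names
        sel = np.flatnonzero(st.selected)
        pd.DataFrame(
            {
                "label_i": ids[idx.rows[sel]],
                "name_i": [names[i] for i in idx.rows[sel]],
                "label_j": ids[idx.cols[sel]],
                "name_j": [names[j] for j in idx.cols[sel]],
                "mean_patient": st.mean_patient[sel],
                "mean_control": st.mean_control[sel],
                "p_value": st.p[sel],
            }
        ).to_csv(
            os.path.join(cfg.out_dir, f"selected_{mod}.tsv"), sep="\t", index=False
        )
        if cfg.run_nbs:
            res = nbs_correct(
                X, ds.labels, idx, primary_p=cfg.alpha,
                n_perm=cfg.n_perm, seed=cfg.seed,
            )
            nbs_summary[mod] = {
                "n_components": len(res.components),
                "component_sizes": res.component_sizes.tolist(),
                "component_pvalues": res.component_pvalues.tolist(),
                "n_significant": len(res.significant),
            }
    timings["selection"] = time.time() - t

    # --- classification ----------------------------------------------------
    t = time.time()
    feats = {m: ds.features[m] for m in cfg.modalities}
    report = nested_loocv(
        feats, ds.labels, C_grid=cfg.c_grid(),
        beta_step=cfg.beta_step, alpha_select=cfg.alpha,
    )
    timings["classify"] = time.time() - t

    # --- consensus ----------------------------------------------------------
    t = time.time()
    consensus_counts = {}
    for mod in cfg.modalities:
        rep = annotate_consensus(
            report.fold_masks[mod], ds.features[mod], ds.labels, parcellation, mod
        )
        rep.table.to_csv(
            os.path.join(cfg.out_dir, f"consensus_{mod}.tsv"), sep="\t", index=False
        )
        consensus_counts[mod] = rep.edge_rows
    timings["consensus"] = time.time() - t

    out = {
        "classification": report.summary(),
        "roc_points": report.roc_points,
        "chosen_params": [
            {"C": C, "beta": list(beta)} for C, beta in report.chosen_params
        ],
        "consensus_counts": consensus_counts,
        "nbs": nbs_summary,
        "n_subjects": ds.n_subjects,
        "provenance": {
            "config_digest": cfg.digest(),
            "seed": cfg.seed,
            "version": __version__,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "wall_s": round(time.time() - t0, 3),
        },
    }
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(out, fh, indent=2)
    cfg.to_yaml(os.path.join(cfg.out_dir, "config.yaml"))
    return out
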