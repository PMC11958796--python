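"""End-to-end orchestration: filters -> typing -> ANOSIM -> superposition ->
landscape -> propensities -> tipping-point analysis.

Every stage is a pure function of (inputs, config, seed); one global seed
fans out to per-stage child seeds through a fixed derivation so stages are
individually reproducible.  ``run_all`` returns a JSON-serialisable summary
plus the intermediate tables, and can write everything to an output
directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_model as dm
from .community_typing import CommunityTyper
from .dissimilarity import anosim, jsd_matrix
from .landscape import class_centroids, class_mean_distance, distances_to_classes
from .superposition import kabsch_fit, predict_and_compare, randomised_rmsd_ci
from .trajectories import (TippingPointClassifier, assign_groups,
                           bootstrap_propensities, classify_trajectories,
                           group_abundance, group_members)

logger = logging.getLogger(__name__)

_STAGES = ("anosim", "centroids", "boot_start", "boot_final", "rmsd_null")


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the end-to-end analysis (defaults follow the study recipe)."""

    asv_min_reads: int = 100
    sample_min_reads: int = 10000
    joint_asv_filter: bool = True     # ASV filter across start+final jointly
    jsd_base: object = 2
    sqrt_distance: bool = True
    k_min: int = 2
    k_max: int = 10
    pin_k_start: int | None = None
    pin_k_final: int | None = None
    fit_replicate: int = 1            # replicate used to fit the superposition
    landscape_replicate: int = 1
    n_permutations: int = 1000
    n_randomisations: int = 50
    n_bootstrap: int = 1000
    centroid_depth: int = 10000
    sf1_threshold: float = 0.125
    cosmo_threshold: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_permutations", "n_randomisations", "n_bootstrap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    summary: dict
    tables: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            fh.write(summary_json(self.summary))
        for name, obj in self.tables.items():
            if isinstance(obj, pd.DataFrame) or isinstance(obj, pd.Series):
                obj.to_csv(out / f"{name}.tsv", sep="\t")


def summary_json(summary: dict) -> str:
    return json.dumps(summary, sort_keys=True, indent=2, default=_json_safe)


def _json_safe(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % 2**31)
            for name, c in zip(_STAGES, children)}


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Recode cluster labels so 1 is the largest class, 2 the next, ..."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    mapping = {old: i + 1 for i, old in enumerate(order)}
    return np.array([mapping[v] for v in labels])


def apply_filters(start: dm.CountTable, final: dm.CountTable,
                  config: PipelineConfig) -> tuple:
    """The quality cascade: ASV filter (jointly by default), sample filter."""
    if list(start.asv_ids) != list(final.asv_ids):
        raise ValueError("start and final tables must share ASV columns")
    if config.joint_asv_filter:
        joint = dm.CountTable(pd.concat([start.data, final.data]))
        joint = dm.filter_asvs_min_reads(joint, config.asv_min_reads)
        keep = joint.asv_ids
        start = start.select_asvs(keep)
        final = final.select_asvs(keep)
    else:
        start = dm.filter_asvs_min_reads(start, config.asv_min_reads)
        final = dm.filter_asvs_min_reads(final, config.asv_min_reads)
    start = dm.filter_samples_min_reads(start, config.sample_min_reads)
    final = dm.filter_samples_min_reads(final, config.sample_min_reads)
    return start, final


def run_all(start: dm.CountTable, final: dm.CountTable,
            metadata: dm.SampleMetadata, config: PipelineConfig | None = None,
            outdir=None) -> PipelineResult:
    """Execute every stage and collect a machine-readable summary."""
    cfg = config or PipelineConfig()
    seeds = _stage_seeds(cfg.seed)
    t0 = time.perf_counter()
    summary: dict = {"seed": cfg.seed}
    tables: dict = {}

    def tick(stage):
        logger.info("[%6.1fs] %s", time.perf_counter() - t0, stage)

    # ---- filters -------------------------------------------------------
    n_asvs_raw = len(start.asv_ids)
    start_f, final_f = apply_filters(start, final, cfg)
    summary["filters"] = {
        "n_asvs_raw": n_asvs_raw,
        "n_asvs_kept": len(start_f.asv_ids),
        "n_start_samples": len(start_f.sample_ids),
        "n_final_samples": len(final_f.sample_ids),
    }
    start_rel = dm.to_relative(start_f)
    final_rel = dm.to_relative(final_f)
    tick("filters")

    # ---- dissimilarities + typing -------------------------------------
    d_start = jsd_matrix(start_rel, base=cfg.jsd_base,
                         as_distance=cfg.sqrt_distance)
    d_final = jsd_matrix(final_rel, base=cfg.jsd_base,
                         as_distance=cfg.sqrt_distance)
    typing = {}
    labels = {}
    for name, d, pin in (("start", d_start, cfg.pin_k_start),
                         ("final", d_final, cfg.pin_k_final)):
        k_max = min(cfg.k_max, len(d.ids) - 1)
        typer = CommunityTyper(k_min=cfg.k_min, k_max=k_max, pin_k=pin).fit(d)
        lab = _relabel_by_size(typer.labels_)
        labels[name] = pd.Series(lab, index=pd.Index(list(d.ids),
                                                     name="sample_id"),
                                 name="class")
        sizes = pd.Series(lab).value_counts().sort_index()
        typing[name] = {
            "k_opt": typer.k_opt_,
            "k_used": typer.k_used_,
            "ch_by_k": {str(k): v for k, v in typer.ch_by_k_.items()},
            "local_maxima": list(typer.local_maxima_),
            "class_sizes": {str(k): int(v) for k, v in sizes.items()},
        }
        tables[f"classes_{name}"] = labels[name]
    summary["typing"] = typing
    tick("typing")

    # ---- ANOSIM --------------------------------------------------------
    meta = metadata.data
    parent_of = meta.loc[list(d_final.ids), "parent_id"]
    replicate_of = meta.loc[list(d_final.ids), "replicate"].astype(int)
    an = {}
    groupings = {
        "start_classes": (d_start, labels["start"].to_numpy()),
        "final_classes": (d_final, labels["final"].to_numpy()),
        "parent_grouping": (d_final, parent_of.to_numpy()),
        "replicate_grouping": (d_final, replicate_of.to_numpy()),
    }
    for i, (name, (d, grp)) in enumerate(groupings.items()):
        res = anosim(d, grp, n_perm=cfg.n_permutations,
                     seed=seeds["anosim"] + i)
        an[name] = {"r": res.r, "p_value": res.p_value,
                    "n_groups": res.n_groups}
    summary["anosim"] = an
    tick("anosim")

    # ---- trajectories (typing of parents) ------------------------------
    n_reps = metadata.replicate_map().shape[1]
    traj = classify_trajectories(metadata, labels["final"],
                                 n_replicates=n_reps)
    summary["trajectories"] = {
        "counts": {str(k): int(v) for k, v in sorted(traj.counts().items())},
        "n_excluded": len(traj.excluded),
    }
    tables["trajectory_types"] = traj.table
    tick("trajectories")

    # ---- superposition -------------------------------------------------
    rep_map = metadata.replicate_map()
    parents = [p for p in traj.table.index
               if p in set(start_rel.sample_ids)
               and all(s in set(final_rel.sample_ids)
                       for s in rep_map.loc[p].dropna())]
    x = start_rel.select_samples(parents)
    rep_tables = {int(r): final_rel.select_samples(
        [rep_map.loc[p, r] for p in parents])
        for r in rep_map.columns}
    fit_rep = cfg.fit_replicate
    fit = kabsch_fit(x.abund, rep_tables[fit_rep].abund)
    ci = randomised_rmsd_ci(x.abund, rep_tables[fit_rep].abund,
                            n_rand=cfg.n_randomisations,
                            seed=seeds["rmsd_null"])
    holdouts = {str(r): t.abund for r, t in rep_tables.items()
                if r != fit_rep}
    comps = predict_and_compare(x.abund, fit, holdouts)
    summary["superposition"] = {
        "fit_replicate": fit_rep,
        "n_pairs": len(parents),
        "rmsd": fit.rmsd_,
        "null_ci": [ci[0], ci[1]],
        "n_randomisations": cfg.n_randomisations,
        "components": [
            {"replicate": c.replicate_id, "component": c.component_index,
             "r_squared": c.r_squared, "p_value": c.p_value,
             "slope": c.slope} for c in comps],
    }
    tables["superposition_components"] = pd.DataFrame(
        [c.__dict__ for c in comps])
    tick("superposition")

    # ---- landscape -----------------------------------------------------
    lrep = cfg.landscape_replicate
    rep_ids = [rep_map.loc[p, lrep] for p in parents]
    final_rep = final_rel.select_samples(rep_ids)
    rep_labels = labels["final"].loc[rep_ids]
    cents = class_centroids(final_rep, rep_labels,
                            depth=cfg.centroid_depth, seed=seeds["centroids"])
    positions = distances_to_classes(x, final_rep, rep_labels,
                                     centroids=cents, base=cfg.jsd_base)
    cmd = class_mean_distance(x, labels["start"].loc[parents],
                              final_rep, rep_labels, base=cfg.jsd_base)
    summary["landscape"] = {
        "replicate": lrep,
        "class_mean_distance": {
            str(i): {str(j): float(cmd.loc[i, j]) for j in cmd.columns}
            for i in cmd.index},
    }
    tables["landscape_positions"] = positions.set_index("sample_id")
    tables["class_mean_distance"] = cmd
    tick("landscape")

    # ---- propensities --------------------------------------------------
    start_typed = start_f.select_samples(
        [p for p in start_f.sample_ids if p in traj.sample_types.index])
    final_typed = final_f.select_samples(
        [s for s in final_f.sample_ids if s in traj.sample_types.index])
    pt_start = bootstrap_propensities(start_typed, traj,
                                      n_boot=cfg.n_bootstrap,
                                      seed=seeds["boot_start"])
    pt_final = bootstrap_propensities(final_typed, traj,
                                      n_boot=cfg.n_bootstrap,
                                      seed=seeds["boot_final"])
    groups = assign_groups(pt_start, pt_final)
    sf1 = group_members(groups, "SF1")
    cosmo = group_members(groups, "cosmopolitan")
    summary["groups"] = {
        "n_sf1": len(sf1), "n_cosmopolitan": len(cosmo),
        "sf1_members": sorted(sf1),
        "cosmopolitan_members": sorted(cosmo),
        "group_sizes": {str(k): int(v)
                        for k, v in groups["group"].value_counts().items()},
    }
    tables["propensities_start"] = pt_start.set_index(["asv_id", "traj_type"])
    tables["propensities_final"] = pt_final.set_index(["asv_id", "traj_type"])
    tables["propensity_groups"] = groups
    tick("propensities")

    # ---- tipping-point classification ----------------------------------
    sums = pd.DataFrame({
        "sf1_start": group_abundance(x, sf1),
        "cosmo_start": group_abundance(x, cosmo),
        "sf1_final": group_abundance(final_rel, sf1, metadata,
                                     average_replicates=True).reindex(parents),
        "cosmo_final": group_abundance(final_rel, cosmo, metadata,
                                       average_replicates=True).reindex(parents),
    })
    clf = TippingPointClassifier(sf1_threshold=cfg.sf1_threshold,
                                 cosmo_threshold=cfg.cosmo_threshold).fit(
        sums[["sf1_final", "cosmo_final"]].to_numpy())
    sums["predicted"] = clf.predict(
        sums[["sf1_final", "cosmo_final"]].to_numpy())
    sums["observed"] = traj.types.reindex(sums.index)
    obs, pred = sums["observed"], sums["predicted"]
    conv = obs.isin(["C1", "C2"])
    confusion = {
        str(o): {str(p): int(((obs == o) & (pred == p)).sum())
                 for p in sorted(pred.unique())}
        for o in sorted(obs.unique())}
    summary["tipping"] = {
        "sf1_threshold": cfg.sf1_threshold,
        "cosmo_threshold": cfg.cosmo_threshold,
        "accuracy_all": float((obs == pred).mean()),
        "accuracy_convergent": (float((obs[conv] == pred[conv]).mean())
                                if conv.any() else None),
        "confusion": confusion,
    }
    tables["group_sums"] = sums
    tick("tipping")

    result = PipelineResult(summary, tables)
    if outdir is not None:
        result.write(outdir)
    return result
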