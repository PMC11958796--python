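"""Synthetic replicated-community experiments with planted ground truth.

The generator emulates the structure of the real experiment — hundreds of
parent communities in a handful of compositional classes, each revived in
four replicates that collapse onto two final classes — with a hierarchical
Dirichlet-multinomial model over three blocks of ASVs:

* an *S&F1* block whose summed abundance tips a community toward final
  class 1,
* a *cosmopolitan* block, present in essentially every community but
  abundant only in final class 2,
* a *background* block whose class-specific composition defines the
  starting community classes.

Each parent draws block masses from one of three archetypes (S&F1-heavy,
cosmopolitan-heavy, balanced); the balanced archetype straddles the planted
tipping point and produces the divergent trajectories.  Replicate fates are
drawn from a logistic function of the parent's S&F1-minus-cosmopolitan mass
contrast, optionally combined with a start-class transition matrix, so
threshold behaviour is planted and recoverable.  Final compositions blend
the final-class base with the parent's own profile (``parent_carryover``),
which is what makes replicate sets cluster by parent and final compositions
predictable from starting ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import adjusted_rand_score

from .data_model import CountTable, FINAL, SampleMetadata, START

__all__ = ["SimulationConfig", "SimulationTruth", "simulate",
           "fixture_config", "mixture_config", "class_agreement",
           "group_recovery", "trajectory_accuracy"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted community-landscape experiment."""

    n_parents: int = 275
    n_replicates: int = 4
    n_asvs: int = 300
    reads_per_sample: int = 15000
    n_start_classes: int = 5
    n_final_classes: int = 2
    start_class_probs: tuple = (0.30, 0.14, 0.14, 0.22, 0.20)
    sf1_size: int = 20
    cosmo_size: int = 12
    # parent block-mass archetypes: (S&F1-heavy, cosmopolitan-heavy, balanced)
    archetype_probs: tuple = (0.55, 0.28, 0.17)
    archetype_sf1_mass: tuple = (0.30, 0.004, 0.14)
    archetype_cosmo_mass: tuple = (0.05, 0.26, 0.14)
    archetype_mass_cv: float = 0.25  # lognormal spread of parent block masses
    # Dirichlet concentrations: block masses, and within-block compositions
    theta_mass: float = 100.0
    theta_sf1: float = 8.0
    theta_cosmo: float = 300.0
    theta_bg: float = 30.0
    sf1_profile_conc: float = 5.0
    cosmo_profile_conc: float = 10.0
    # background = abundant core shared by all classes + a flat class-specific
    # tail: classes differ in many individually-rare ASVs (large JSD) while
    # the dominant Euclidean axes stay with the S&F1/cosmopolitan blocks
    bg_shared_frac: float = 0.6
    bg_shared_conc: float = 2.0
    bg_class_conc: float = 1.0
    # final-class block masses: the boosted block dominates its attractor
    sf1_mass_base: float = 0.015
    sf1_boost: float = 30.0
    cosmo_mass_base: float = 0.04
    cosmo_boost: float = 7.0
    transition_probs: tuple | None = None  # rows: start class -> final class
    tipping_noise: float = 0.04  # logistic temperature; 0 = hard threshold
    parent_carryover: float = 0.40
    seed: int = 0

    def __post_init__(self):
        if self.sf1_size + self.cosmo_size >= self.n_asvs:
            raise ValueError("group sizes must leave room for background ASVs")
        if self.sf1_boost < 1 or self.cosmo_boost < 1:
            raise ValueError("boosts must be >= 1")
        if self.start_class_probs is not None:
            p = np.asarray(self.start_class_probs, dtype=float)
            if p.size != self.n_start_classes or abs(p.sum() - 1) > 1e-9:
                raise ValueError("start_class_probs must sum to 1 with one "
                                 "entry per start class")
        if self.transition_probs is not None:
            t = np.asarray(self.transition_probs, dtype=float)
            if t.shape != (self.n_start_classes, self.n_final_classes):
                raise ValueError("transition_probs must be start x final")
            if not np.allclose(t.sum(axis=1), 1.0):
                raise ValueError("transition_probs rows must sum to 1")
        m1 = self.sf1_mass_base * self.sf1_boost
        m2 = self.cosmo_mass_base * self.cosmo_boost
        if m1 + self.cosmo_mass_base >= 1 or m2 + self.sf1_mass_base >= 1:
            raise ValueError("boosted block masses exceed the simplex")


@dataclass(frozen=True)
class SimulationTruth:
    """Planted ground truth accompanying a simulated experiment."""

    parents: pd.DataFrame     # start_class, rep fates, type, planted sums
    final_class: pd.Series    # final sample id -> planted final class (1-based)
    asv_groups: pd.Series     # asv id -> {"SF1", "cosmopolitan", "background"}
    config: SimulationConfig

    @property
    def start_class(self) -> pd.Series:
        return self.parents["start_class"]

    @property
    def traj_type(self) -> pd.Series:
        return self.parents["type"]

    def group(self, name: str) -> list:
        return list(self.asv_groups.index[self.asv_groups == name])


def fixture_config(size: str = "small", seed: int = 0) -> SimulationConfig:
    """Canonical fixture configurations.

    "small" (40 parents) is a smoke-test fixture, "medium" (150 parents) is
    the standard end-to-end validation fixture, and "full" matches the
    experimental design scale (275 parents, 4 replicates, 15,000 reads).
    """
    if size == "full":
        return SimulationConfig(seed=seed)
    if size == "medium":
        return SimulationConfig(n_parents=150, n_asvs=200, seed=seed)
    if size == "small":
        return SimulationConfig(n_parents=40, n_asvs=120, sf1_size=12,
                                cosmo_size=8, seed=seed)
    raise ValueError("size must be 'small', 'medium' or 'full'")


def mixture_config(n_classes: int, n_samples: int = 150,
                   seed: int = 0) -> SimulationConfig:
    """Pure Dirichlet-mixture conditions for class-recovery studies.

    The tipping archetypes are muted (equal block masses) and classes are
    equiprobable with sparse, nearly disjoint background tails, so the
    starting table is a k-class Dirichlet-multinomial mixture whose planted
    labels a community-typing stage should recover.
    """
    return SimulationConfig(
        n_parents=n_samples, n_asvs=200, sf1_size=20, cosmo_size=12,
        n_start_classes=n_classes,
        start_class_probs=tuple([1.0 / n_classes] * n_classes),
        archetype_sf1_mass=(0.08, 0.08, 0.08),
        archetype_cosmo_mass=(0.08, 0.08, 0.08),
        bg_shared_frac=0.3, bg_class_conc=0.3, theta_bg=60.0, seed=seed)


def _tip_probability(contrast: np.ndarray, noise: float) -> np.ndarray:
    if noise == 0:
        return np.where(contrast > 0, 1.0,
                        np.where(contrast < 0, 0.0, 0.5))
    return expit(contrast / noise)


def simulate(config: SimulationConfig, seed: int | None = None):
    """Generate (start CountTable, final CountTable, metadata, truth)."""
    cfg = config if seed is None else replace(config, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    n_bg = cfg.n_asvs - cfg.sf1_size - cfg.cosmo_size
    f_classes = cfg.n_final_classes

    # shared within-block target profiles and class-specific backgrounds
    g_sf1 = rng.dirichlet(np.full(cfg.sf1_size, cfg.sf1_profile_conc))
    g_cosmo = rng.dirichlet(np.full(cfg.cosmo_size, cfg.cosmo_profile_conc))
    bg_core = rng.dirichlet(np.full(n_bg, cfg.bg_shared_conc))

    def bg_base():
        tail = rng.dirichlet(np.full(n_bg, cfg.bg_class_conc))
        return cfg.bg_shared_frac * bg_core + (1 - cfg.bg_shared_frac) * tail

    bg_start = np.stack([bg_base() for _ in range(cfg.n_start_classes)])
    bg_final = np.stack([bg_base() for _ in range(f_classes)])

    probs = (np.full(cfg.n_start_classes, 1 / cfg.n_start_classes)
             if cfg.start_class_probs is None
             else np.asarray(cfg.start_class_probs, dtype=float))
    start_class = rng.choice(cfg.n_start_classes, size=cfg.n_parents, p=probs)
    # archetypes are allocated proportionally within every start class so the
    # planted tipping variable is orthogonal to class membership by design
    a_probs = np.asarray(cfg.archetype_probs, dtype=float)
    archetype = np.empty(cfg.n_parents, dtype=int)
    for k in range(cfg.n_start_classes):
        idx = np.flatnonzero(start_class == k)
        quota = a_probs * idx.size
        counts = np.floor(quota).astype(int)
        frac_order = np.argsort(-(quota - counts), kind="stable")
        for j in frac_order[: idx.size - counts.sum()]:
            counts[j] += 1
        alloc = np.repeat(np.arange(a_probs.size), counts)
        rng.shuffle(alloc)
        archetype[idx] = alloc

    trans = (np.full((cfg.n_start_classes, f_classes), 1.0 / f_classes)
             if cfg.transition_probs is None
             else np.asarray(cfg.transition_probs, dtype=float))

    # final-class block-mass targets (class 0 boosts S&F1, class 1 cosmo)
    final_masses = np.empty((f_classes, 2))
    final_masses[:, 0] = cfg.sf1_mass_base
    final_masses[:, 1] = cfg.cosmo_mass_base
    final_masses[0, 0] = cfg.sf1_mass_base * cfg.sf1_boost
    if f_classes > 1:
        final_masses[1, 1] = cfg.cosmo_mass_base * cfg.cosmo_boost

    def dirichlet(alpha):
        a = np.maximum(np.asarray(alpha, dtype=float), 1e-300)
        draw = rng.dirichlet(a)
        if not np.isfinite(draw).all():  # numerical underflow guard
            draw = np.where(np.isfinite(draw), draw, 0.0)
            draw = a / a.sum() if draw.sum() == 0 else draw / draw.sum()
        return draw

    parent_ids = [f"S{i + 1:03d}" for i in range(cfg.n_parents)]
    start_rows, final_rows = [], []
    final_ids, meta_rows = [], []
    parent_truth = {}
    gamma = cfg.parent_carryover

    for i, pid in enumerate(parent_ids):
        k = start_class[i]
        a = archetype[i]
        m_sf1 = np.clip(cfg.archetype_sf1_mass[a]
                        * np.exp(rng.normal(0.0, cfg.archetype_mass_cv)),
                        5e-4, 0.6)
        m_cosmo = np.clip(cfg.archetype_cosmo_mass[a]
                          * np.exp(rng.normal(0.0, cfg.archetype_mass_cv)),
                          5e-4, 0.6)
        centre = np.array([m_sf1, m_cosmo, 1.0 - m_sf1 - m_cosmo])
        masses = dirichlet(cfg.theta_mass * centre)
        w_sf1 = dirichlet(cfg.theta_sf1 * g_sf1)
        w_cosmo = dirichlet(cfg.theta_cosmo * g_cosmo)
        w_bg = dirichlet(cfg.theta_bg * bg_start[k])
        profile = np.concatenate([masses[0] * w_sf1, masses[1] * w_cosmo,
                                  masses[2] * w_bg])
        start_rows.append(rng.multinomial(cfg.reads_per_sample, profile))
        meta_rows.append((pid, START, pid, pd.NA))

        tip = float(_tip_probability(np.array(masses[0] - masses[1]),
                                     cfg.tipping_noise))
        weights = np.full(f_classes, (1.0 - tip) / max(f_classes - 1, 1))
        weights[0] = tip
        p_final = trans[k] * weights
        total = p_final.sum()
        p_final = (p_final / total if total > 0
                   else np.full(f_classes, 1.0 / f_classes))

        fates = rng.choice(f_classes, size=cfg.n_replicates, p=p_final)
        rec = {"start_class": int(k) + 1, "archetype": int(a),
               "sf1_mass": float(masses[0]), "cosmo_mass": float(masses[1]),
               "tip_p1": tip}
        for j in range(cfg.n_replicates):
            fc = int(fates[j])
            sid = f"{pid}_r{j + 1}"
            fm = np.array([final_masses[fc, 0], final_masses[fc, 1], 0.0])
            fm[2] = 1.0 - fm[0] - fm[1]
            centre_f = (1 - gamma) * fm + gamma * masses
            masses_f = dirichlet(cfg.theta_mass * centre_f)
            wf_sf1 = dirichlet(cfg.theta_sf1 * g_sf1)
            wf_cosmo = dirichlet(cfg.theta_cosmo * g_cosmo)
            bg_mix = (1 - gamma) * bg_final[fc] + gamma * w_bg
            wf_bg = dirichlet(cfg.theta_bg * bg_mix)
            profile_f = np.concatenate([masses_f[0] * wf_sf1,
                                        masses_f[1] * wf_cosmo,
                                        masses_f[2] * wf_bg])
            final_rows.append(rng.multinomial(cfg.reads_per_sample, profile_f))
            final_ids.append(sid)
            meta_rows.append((sid, FINAL, pid, j + 1))
            rec[f"rep_{j + 1}"] = fc + 1
        uniq = set(int(f) for f in fates)
        rec["type"] = f"C{fates[0] + 1}" if len(uniq) == 1 else "D"
        parent_truth[pid] = rec

    asv_ids = ([f"SF1_{i + 1:03d}" for i in range(cfg.sf1_size)]
               + [f"COS_{i + 1:03d}" for i in range(cfg.cosmo_size)]
               + [f"BG_{i + 1:04d}" for i in range(n_bg)])
    start = CountTable(pd.DataFrame(np.asarray(start_rows),
                                    index=parent_ids, columns=asv_ids))
    final = CountTable(pd.DataFrame(np.asarray(final_rows),
                                    index=final_ids, columns=asv_ids))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "time_point",
                                            "parent_id", "replicate"]
                        ).set_index("sample_id")
    meta["replicate"] = meta["replicate"].astype("Int64")
    metadata = SampleMetadata(meta)

    parents = pd.DataFrame.from_dict(parent_truth, orient="index")
    parents.index.name = "parent_id"
    final_class = pd.Series(
        {f"{pid}_r{j + 1}": parent_truth[pid][f"rep_{j + 1}"]
         for pid in parent_ids for j in range(cfg.n_replicates)},
        name="final_class")
    groups = pd.Series(
        ["SF1"] * cfg.sf1_size + ["cosmopolitan"] * cfg.cosmo_size
        + ["background"] * n_bg,
        index=pd.Index(asv_ids, name="asv_id"), name="group")
    truth = SimulationTruth(parents, final_class, groups, cfg)
    return start, final, metadata, truth


# ---------------------------------------------------------------------------
# Scoring inferred results against the planted truth
# ---------------------------------------------------------------------------

def class_agreement(inferred, truth) -> float:
    """Adjusted Rand index between an inferred and the planted labelling."""
    a = pd.Series(inferred)
    b = pd.Series(truth)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no shared sample ids between labellings")
    if len(common) < len(a.index.union(b.index)):
        raise ValueError("labellings cover different sample sets")
    return float(adjusted_rand_score(b.loc[common], a.loc[common]))


def group_recovery(inferred_members, true_members) -> dict:
    """Precision and recall of an inferred ASV group against the truth."""
    inf_set, true_set = set(inferred_members), set(true_members)
    tp = len(inf_set & true_set)
    precision = tp / len(inf_set) if inf_set else 0.0
    recall = tp / len(true_set) if true_set else 1.0
    return {"precision": precision, "recall": recall,
            "n_inferred": len(inf_set), "n_true": len(true_set)}


def trajectory_accuracy(predicted, truth, restrict_to=None) -> float:
    """Fraction of trajectories whose predicted type matches the truth.

    ``restrict_to`` limits scoring to a set of true types (e.g. the
    convergent ones, where the tipping thresholds claim predictivity).
    """
    pred = pd.Series(predicted)
    true = pd.Series(truth)
    common = pred.index.intersection(true.index)
    if len(common) == 0:
        raise ValueError("no shared trajectory ids")
    pred, true = pred.loc[common], true.loc[common]
    if restrict_to is not None:
        mask = true.isin(list(restrict_to))
        pred, true = pred[mask], true[mask]
        if len(true) == 0:
            raise ValueError("no trajectories of the requested types")
    return float((pred.to_numpy() == true.to_numpy()).mean())
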