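"""Trajectory typing, ASV propensities, propensity groups and tipping points.

A *trajectory* is one starting community plus its replicate final
communities.  It is convergent to class c (type "Cc") when every replicate
ends in final class c, and divergent ("D") otherwise.  The *propensity* of
an ASV i for trajectory type T at time t is the log-fold change of its
occurrence probability conditional on the type,

    prop_i(T, t) = log[ P(X_i(t) > 0 | community in T) / P(X_i(t) > 0) ],

estimated from presence frequencies and bootstrapped by resampling
communities with replacement.  ASVs with significantly positive propensity
for type C1 at both time points form the "S&F1" group; ASVs whose
propensities are non-negative for every type at both time points (taxa
present essentially everywhere — propensities pinned at zero by ubiquity)
form the "cosmopolitan" group.  Summed relative abundances of the two
groups separate the trajectory types via two tipping-point thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .community_typing import ClassAssignment
from .data_model import CountTable, RelAbundTable, SampleMetadata

logger = logging.getLogger(__name__)

DIVERGENT = "D"


def _labels_series(classes) -> pd.Series:
    if isinstance(classes, ClassAssignment):
        return classes.as_series()
    return pd.Series(classes)


@dataclass(frozen=True)
class TrajectorySet:
    """Typed trajectories: parents, their replicate fates, and a label per
    member community (the parent and every replicate share the type)."""

    table: pd.DataFrame          # index parent_id; replicate class columns + type
    sample_types: pd.Series      # sample_id -> type, start and final samples
    excluded: list = field(default_factory=list)

    @property
    def types(self) -> pd.Series:
        return self.table["type"]

    def counts(self) -> dict:
        return self.table["type"].value_counts().to_dict()


def classify_trajectories(meta: SampleMetadata, final_classes,
                          n_replicates: int = 4) -> TrajectorySet:
    """Type each parent community from its replicates' final classes.

    Parents whose ``n_replicates`` final samples all carry a class label are
    typed "Cc" (all replicates in class c) or "D"; parents with missing
    replicates or unlabelled samples are excluded and logged.
    """
    labels = _labels_series(final_classes)
    rep_map = meta.replicate_map()
    rows, sample_types, excluded = {}, {}, []
    for parent, reps in rep_map.iterrows():
        ids = reps.dropna()
        classes = labels.reindex(ids.to_numpy()).dropna()
        if len(ids) < n_replicates or len(classes) < n_replicates:
            excluded.append(parent)
            continue
        uniq = classes.unique()
        ttype = f"C{uniq[0]}" if len(uniq) == 1 else DIVERGENT
        row = {f"rep_{r}": labels.get(s, None) for r, s in ids.items()}
        row["type"] = ttype
        rows[parent] = row
        sample_types[parent] = ttype
        for s in ids:
            sample_types[s] = ttype
    if excluded:
        logger.warning("%d parents excluded from trajectory typing (e.g. %s)",
                       len(excluded), excluded[:3])
    if not rows:
        raise ValueError("no parent has a complete set of labelled replicates")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parent_id"
    return TrajectorySet(table, pd.Series(sample_types, name="type"),
                         excluded)


# ---------------------------------------------------------------------------
# Propensities
# ---------------------------------------------------------------------------

def _presence_and_types(t, types, min_count: int):
    if isinstance(t, CountTable):
        mat, sample_ids, asv_ids = t.counts, t.sample_ids, t.asv_ids
    else:
        df = pd.DataFrame(t)
        mat, sample_ids, asv_ids = df.to_numpy(), list(df.index), list(df.columns)
    types = pd.Series(types) if not isinstance(types, pd.Series) else types
    tvec = types.reindex(sample_ids)
    if tvec.isna().any():
        missing = list(tvec.index[tvec.isna()])
        raise ValueError(f"samples without a trajectory type: {missing[:5]}")
    presence = mat >= min_count
    keep = presence.any(axis=0)
    if not keep.all():
        logger.info("dropping %d ASVs absent from every community",
                    int((~keep).sum()))
    presence = presence[:, keep]
    asv_ids = [a for a, k in zip(asv_ids, keep) if k]
    uniq, codes = np.unique(tvec.to_numpy(), return_inverse=True)
    return presence.astype(float), codes, list(uniq), asv_ids


def _propensity_matrix(presence, codes, n_types):
    """Per-type and marginal presence frequencies -> log-ratio matrix."""
    counts = np.bincount(codes, minlength=n_types).astype(float)
    if np.any(counts == 0):
        raise ValueError("empty trajectory-type stratum")
    marg = presence.mean(axis=0)
    cond = np.stack([presence[codes == t].mean(axis=0)
                     for t in range(n_types)])
    with np.errstate(divide="ignore", invalid="ignore"):
        # an ASV can vanish from a bootstrap resample: 0/0 -> NaN, which the
        # percentile step ignores
        prop = np.log(cond) - np.log(marg)
    return prop, cond, marg, counts


def propensity(t, traj, min_count: int = 1, base: str = "e") -> pd.DataFrame:
    """Point-estimate propensities of every ASV for every trajectory type.

    ``traj`` is a TrajectorySet or a sample -> type mapping covering every
    community in the table.  The log is natural by default (``base="2"``
    rescales).  A type never containing the ASV yields -inf.
    """
    types = traj.sample_types if isinstance(traj, TrajectorySet) else traj
    presence, codes, uniq, asv_ids = _presence_and_types(t, types, min_count)
    prop, cond, marg, counts = _propensity_matrix(presence, codes, len(uniq))
    if base in (2, "2"):
        prop = prop / np.log(2.0)
    elif base not in ("e", np.e):
        raise ValueError("base must be 'e' or 2")
    frames = []
    for ti, tname in enumerate(uniq):
        frames.append(pd.DataFrame({
            "asv_id": asv_ids,
            "traj_type": tname,
            "propensity": prop[ti],
            "p_present_type": cond[ti],
            "p_present": marg,
            "n_type": int(counts[ti]),
        }))
    return pd.concat(frames, ignore_index=True)


class PropensityBootstrap(BaseEstimator):
    """Bootstrap CIs for ASV-by-trajectory-type propensities.

    ``fit(X, y)`` takes a communities x ASVs count (or presence) matrix and
    a type label per community.  Communities are resampled with replacement,
    labels travelling with rows; replicates where a type stratum vanishes
    are redrawn (and counted in ``n_redraws_``).

    Attributes: ``propensity_`` (types x ASVs), ``ci_low_``, ``ci_high_``,
    ``significant_positive_`` (ci_low > 0), ``types_``, ``asv_ids_``.
    """

    def __init__(self, n_boot: int = 1000, seed=None, ci=(2.5, 97.5),
                 min_count: int = 1):
        self.n_boot = n_boot
        self.seed = seed
        self.ci = ci
        self.min_count = min_count

    def fit(self, X, y):
        presence, codes, uniq, asv_ids = _presence_and_types(
            X, y, self.min_count)
        n, p = presence.shape
        k = len(uniq)
        prop, cond, marg, counts = _propensity_matrix(presence, codes, k)
        rng = np.random.default_rng(self.seed)
        boots = np.empty((self.n_boot, k, p))
        redraws = 0
        for b in range(self.n_boot):
            while True:
                idx = rng.integers(0, n, size=n)
                if np.all(np.bincount(codes[idx], minlength=k) > 0):
                    break
                redraws += 1
            boots[b] = _propensity_matrix(presence[idx], codes[idx], k)[0]
        if redraws:
            logger.info("redrew %d bootstrap replicates with empty strata",
                        redraws)
        with np.errstate(invalid="ignore"):
            self.ci_low_ = np.nanpercentile(boots, self.ci[0], axis=0)
            self.ci_high_ = np.nanpercentile(boots, self.ci[1], axis=0)
        self.propensity_ = prop
        self.p_present_type_ = cond
        self.p_present_ = marg
        self.stratum_sizes_ = counts
        self.significant_positive_ = self.ci_low_ > 0
        self.types_ = uniq
        self.asv_ids_ = asv_ids
        self.n_redraws_ = redraws
        return self


def bootstrap_propensities(t, traj, n_boot: int = 1000, seed=None,
                           min_count: int = 1) -> pd.DataFrame:
    """Long-format propensity table with bootstrap CIs and significance.

    ``significant_positive`` requires the whole 95% CI above zero;
    ``significant_nonnegative`` allows CIs touching zero from above, the
    signature of ubiquitous (propensity pinned at zero) taxa.
    """
    types = traj.sample_types if isinstance(traj, TrajectorySet) else traj
    est = PropensityBootstrap(n_boot=n_boot, seed=seed,
                              min_count=min_count).fit(t, types)
    frames = []
    for ti, tname in enumerate(est.types_):
        frames.append(pd.DataFrame({
            "asv_id": est.asv_ids_,
            "traj_type": tname,
            "propensity": est.propensity_[ti],
            "ci_low": est.ci_low_[ti],
            "ci_high": est.ci_high_[ti],
            "significant_positive": est.significant_positive_[ti],
            "significant_nonnegative": (
                (est.ci_low_[ti] >= 0) & np.isfinite(est.propensity_[ti])),
            "p_present_type": est.p_present_type_[ti],
            "p_present": est.p_present_,
            "n_type": int(est.stratum_sizes_[ti]),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Propensity groups
# ---------------------------------------------------------------------------

def _flags(pt: pd.DataFrame, column: str) -> pd.DataFrame:
    return pt.pivot(index="asv_id", columns="traj_type", values=column)


def assign_groups(start_pt: pd.DataFrame, final_pt: pd.DataFrame,
                  cosmopolitan_rule: str = "nonnegative") -> pd.DataFrame:
    """Assign each ASV to a propensity group from its six significance cells.

    Groups (mutually exclusive, assigned in priority order):

    * ``cosmopolitan`` — associated with all three trajectory types at both
      time points.  By default the cell criterion is a non-negative CI with
      finite propensity (``cosmopolitan_rule="nonnegative"``), because the
      law of total probability pins the propensities of taxa present in
      every community at exactly zero, so a strictly positive CI in all six
      cells is unattainable; ``"strict"`` applies ci_low > 0 anyway.
    * ``SF1`` / ``SF2`` — significantly positive for C1 (resp. C2) at both
      start and final.
    * otherwise a signature label joining the significant cells, e.g.
      ``start-C1`` or ``start-C1+final-D``, or ``none``.

    Returns a frame indexed by ASV with the six boolean cells, the
    signature and the group.
    """
    if cosmopolitan_rule not in ("nonnegative", "strict"):
        raise ValueError("cosmopolitan_rule must be 'nonnegative' or 'strict'")
    sig = {"start": _flags(start_pt, "significant_positive"),
           "final": _flags(final_pt, "significant_positive")}
    cosmo_col = ("significant_nonnegative"
                 if cosmopolitan_rule == "nonnegative"
                 else "significant_positive")
    nneg = {"start": _flags(start_pt, cosmo_col),
            "final": _flags(final_pt, cosmo_col)}
    asvs = sig["start"].index.intersection(sig["final"].index)
    dropped = len(sig["start"].index.union(sig["final"].index)) - len(asvs)
    if dropped:
        logger.warning("%d ASVs present in only one time point were dropped",
                       dropped)
    types = sorted(set(sig["start"].columns) & set(sig["final"].columns))
    rows = []
    for asv in asvs:
        cells = {(tp, ty): bool(sig[tp].loc[asv, ty])
                 for tp in ("start", "final") for ty in types}
        cosmo = all(bool(nneg[tp].loc[asv, ty]) and not
                    pd.isna(nneg[tp].loc[asv, ty])
                    for tp in ("start", "final") for ty in types)
        signature = "+".join(f"{tp}-{ty}" for tp in ("start", "final")
                             for ty in types if cells[(tp, ty)]) or "none"
        if cosmo:
            group = "cosmopolitan"
        elif cells.get(("start", "C1")) and cells.get(("final", "C1")):
            group = "SF1"
        elif cells.get(("start", "C2")) and cells.get(("final", "C2")):
            group = "SF2"
        else:
            group = signature
        row = {f"sig_{tp}_{ty}": cells[(tp, ty)]
               for tp in ("start", "final") for ty in types}
        row["signature"] = signature
        row["group"] = group
        rows.append(pd.Series(row, name=asv))
    out = pd.DataFrame(rows)
    out.index.name = "asv_id"
    return out


def group_members(groups: pd.DataFrame, name: str) -> list:
    return list(groups.index[groups["group"] == name])


def group_abundance(t: RelAbundTable, group, meta: SampleMetadata | None = None,
                    average_replicates: bool = False) -> pd.Series:
    """Summed relative abundance of a set of ASVs per sample.

    Group members missing from the table contribute zero (logged).  With
    ``average_replicates`` and metadata, final samples are averaged across
    the replicates of each parent and the series is indexed by parent.
    """
    group = list(group)
    have = [g for g in group if g in t.data.columns]
    if len(have) < len(group):
        logger.info("%d group members absent from the table",
                    len(group) - len(have))
    sums = (t.data[have].sum(axis=1) if have
            else pd.Series(0.0, index=t.data.index))
    sums.name = "group_abundance"
    if average_replicates:
        if meta is None:
            raise ValueError("metadata required to average across replicates")
        parents = meta.parents().reindex(sums.index).dropna()
        sums = sums.loc[parents.index].groupby(parents).mean()
        sums.index.name = "parent_id"
    return sums


# ---------------------------------------------------------------------------
# Tipping-point threshold classification
# ---------------------------------------------------------------------------

class TippingPointClassifier(ClassifierMixin, BaseEstimator):
    """Predict trajectory type from (S&F1 sum, cosmopolitan sum).

    The rule follows the observed tipping points: predict C1 when the S&F1
    sum exceeds its threshold while the cosmopolitan sum does not exceed
    its own; C2 in the reverse situation; D (unpredictable) when both or
    neither exceed — unbalanced abundances of the two groups are what makes
    a trajectory predictable.

    With ``optimise=True`` and observed types passed to ``fit``, the two
    thresholds are grid-searched to maximise accuracy (an extension; the
    defaults are the fixed literature thresholds 0.125 and 0.2).
    """

    def __init__(self, sf1_threshold: float = 0.125,
                 cosmo_threshold: float = 0.2, optimise: bool = False,
                 grid_size: int = 40):
        self.sf1_threshold = sf1_threshold
        self.cosmo_threshold = cosmo_threshold
        self.optimise = optimise
        self.grid_size = grid_size

    def fit(self, X, y=None):
        X = self._validate(X)
        self.classes_ = np.array(["C1", "C2", DIVERGENT])
        if self.optimise:
            if y is None:
                raise ValueError("optimise=True requires observed types")
            y = np.asarray(list(y))
            grid = np.linspace(0.0, 1.0, self.grid_size + 1)[1:-1]
            # the configured thresholds always take part, so tuning can
            # never end up worse than the fixed rule
            grid1 = np.append(grid, self.sf1_threshold)
            grid2 = np.append(grid, self.cosmo_threshold)
            best = (-1.0, self.sf1_threshold, self.cosmo_threshold)
            for t1 in grid1:
                for t2 in grid2:
                    acc = float(np.mean(_rule(X, t1, t2) == y))
                    if acc > best[0]:
                        best = (acc, float(t1), float(t2))
            self.best_accuracy_, self.sf1_threshold_, self.cosmo_threshold_ = best
        else:
            self.sf1_threshold_ = float(self.sf1_threshold)
            self.cosmo_threshold_ = float(self.cosmo_threshold)
        return self

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): sf1 and cosmo sums")
        if np.any(X < 0) or np.any(X > 1):
            raise ValueError("group abundance sums must lie in [0, 1]")
        return X

    def predict(self, X) -> np.ndarray:
        X = self._validate(X)
        return _rule(X, self.sf1_threshold_, self.cosmo_threshold_)


def _rule(X: np.ndarray, t1: float, t2: float) -> np.ndarray:
    hi1 = X[:, 0] > t1
    hi2 = X[:, 1] > t2
    out = np.full(X.shape[0], DIVERGENT, dtype=object)
    out[hi1 & ~hi2] = "C1"
    out[~hi1 & hi2] = "C2"
    return out.astype(str)


def threshold_classify(sf1_sum: float, cosmo_sum: float,
                       sf1_threshold: float = 0.125,
                       cosmo_threshold: float = 0.2) -> str:
    """Scalar convenience wrapper around :class:`TippingPointClassifier`."""
    for name, v in (("sf1_sum", sf1_sum), ("cosmo_sum", cosmo_sum)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return str(_rule(np.array([[sf1_sum, cosmo_sum]]), sf1_threshold,
                     cosmo_threshold)[0])
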