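"""Attractor geometry on the compositional landscape.

Final community classes are treated as the neighbourhoods of attractors.
Each class gets a *centroid*: every member is resampled once as a
multinomial draw of ``depth`` reads from its relative abundances, the
per-ASV median of the resampled counts is taken across members, and the
median profile is renormalised.  Starting communities are then positioned
relative to the attractors by their Jensen-Shannon distance to each class
centroid and to each class *border* (the closest member community of the
class, excluding the query itself when it belongs to the class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_typing import ClassAssignment
from .data_model import RelAbundTable
from .dissimilarity import jsd_pair


@dataclass(frozen=True)
class ClassCentroid:
    """Resampled-median centroid of one community class."""

    class_label: object
    abund: pd.Series  # relative abundances over ASVs, sums to 1
    resample_depth: int
    seed: int | None
    n_members: int


def _labels_series(classes) -> pd.Series:
    if isinstance(classes, ClassAssignment):
        return classes.as_series()
    return pd.Series(classes)


def class_centroid(t: RelAbundTable, members, depth: int = 10000,
                   seed: int | None = None, n_resamples: int = 1
                   ) -> ClassCentroid:
    """Centroid of a class: per-ASV median of multinomial resamples.

    One multinomial draw per member by default; ``n_resamples > 1`` averages
    the median profiles over repeated resampling rounds for extra
    robustness.
    """
    members = list(members)
    if not members:
        raise ValueError("empty class has no centroid")
    probs = t.data.loc[members].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(max(1, int(n_resamples))):
        draws = np.stack([rng.multinomial(depth, row / row.sum())
                          for row in probs])
        med = np.median(draws, axis=0)
        total = med.sum()
        if total == 0:
            raise ValueError(
                "degenerate centroid: median resampled count is zero "
                "everywhere (members share no common ASVs)")
        profiles.append(med / total)
    abund = np.mean(profiles, axis=0)
    abund = abund / abund.sum()
    return ClassCentroid(None, pd.Series(abund, index=t.data.columns),
                         depth, seed, len(members))


def class_centroids(t: RelAbundTable, classes, depth: int = 10000,
                    seed: int | None = None) -> dict:
    """Centroid per class label; child seeds derived deterministically."""
    labels = _labels_series(classes)
    ss = np.random.SeedSequence(seed)
    out = {}
    uniq = sorted(pd.unique(labels), key=str)
    children = ss.spawn(len(uniq))
    for lab, child in zip(uniq, children):
        members = list(labels.index[labels == lab])
        cent = class_centroid(t, members, depth=depth,
                              seed=int(child.generate_state(1)[0] % 2**31))
        out[lab] = ClassCentroid(lab, cent.abund, depth, seed, len(members))
    return out


def distances_to_classes(start: RelAbundTable, final: RelAbundTable,
                         final_classes, centroids: dict | None = None,
                         base=2, depth: int = 10000,
                         seed: int | None = None) -> pd.DataFrame:
    """Distance of each start community to every final class.

    Returns a tidy frame with one row per (start sample, final class):
    ``dist_centroid`` (sqrt-JSD to the class centroid) and ``dist_border``
    (minimum sqrt-JSD over the class's member communities, excluding the
    query itself when it appears in the class).
    """
    labels = _labels_series(final_classes)
    unknown = set(labels.index) - set(final.sample_ids)
    if unknown:
        raise ValueError(f"class labels for unknown samples: {sorted(unknown)[:5]}")
    if centroids is None:
        centroids = class_centroids(final, labels, depth=depth, seed=seed)
    missing = set(pd.unique(labels)) - set(centroids)
    if missing:
        raise ValueError(f"no centroid for classes: {sorted(missing, key=str)}")
    rows = []
    fdata = final.data
    for sid in start.sample_ids:
        p = start.data.loc[sid].to_numpy(dtype=float)
        for lab, cent in centroids.items():
            members = [m for m in labels.index[labels == lab] if m != sid]
            if not members:
                raise ValueError(f"class {lab!r} has no non-self members")
            d_border = min(
                np.sqrt(jsd_pair(p, fdata.loc[m].to_numpy(dtype=float),
                                 base=base))
                for m in members)
            d_cent = np.sqrt(jsd_pair(p, cent.abund.to_numpy(), base=base))
            rows.append((sid, lab, float(d_cent), float(d_border)))
    return pd.DataFrame(rows, columns=["sample_id", "final_class",
                                       "dist_centroid", "dist_border"])


def class_mean_distance(a: RelAbundTable, a_classes, b: RelAbundTable,
                        b_classes, base=2) -> pd.DataFrame:
    """Mean pairwise sqrt-JSD between every class of ``a`` and of ``b``.

    Entry (i, j) averages over all cross pairs; pairs of a sample with
    itself (possible when ``a`` and ``b`` share samples) are excluded, so
    with ``a is b`` and one class the single entry is the mean off-diagonal
    distance.
    """
    la, lb = _labels_series(a_classes), _labels_series(b_classes)
    ua = sorted(pd.unique(la), key=str)
    ub = sorted(pd.unique(lb), key=str)
    out = pd.DataFrame(index=pd.Index(ua, name="class_a"),
                       columns=pd.Index(ub, name="class_b"), dtype=float)
    for ca in ua:
        ids_a = list(la.index[la == ca])
        if not ids_a:
            raise ValueError(f"empty class {ca!r}")
        pa = a.data.loc[ids_a]
        for cb in ub:
            ids_b = list(lb.index[lb == cb])
            if not ids_b:
                raise ValueError(f"empty class {cb!r}")
            pb = b.data.loc[ids_b]
            vals = [np.sqrt(jsd_pair(pa.loc[i].to_numpy(dtype=float),
                                     pb.loc[j].to_numpy(dtype=float),
                                     base=base))
                    for i in ids_a for j in ids_b if i != j]
            if not vals:
                raise ValueError(
                    f"classes {ca!r}/{cb!r} contain only self pairs")
            out.loc[ca, cb] = float(np.mean(vals))
    return out
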