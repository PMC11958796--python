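"""Community-class detection: PAM over a dissimilarity matrix, scored by CH.

Compositionally similar communities are grouped into *classes* (the
enterotyping recipe): Partition Around Medoids consumes the square-root
Jensen-Shannon distance matrix directly, and the number of classes is chosen
by scanning k and maximising the Calinski-Harabasz index computed in PCoA
coordinates of the same matrix (the classical CH formula needs a Euclidean
embedding).  Both the global CH maximum and all local maxima are reported,
and k can be pinned, because an analysis may deliberately prefer a coarser
local maximum over the global one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb as _comb

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import calinski_harabasz_score

from .dissimilarity import pcoa


def _as_square(d) -> tuple[np.ndarray, list]:
    if isinstance(d, DistanceMatrix):
        return d.data, list(d.ids)
    mat = np.asarray(d, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("expected a square dissimilarity matrix")
    return mat, [str(i) for i in range(mat.shape[0])]


@dataclass(frozen=True)
class ClassAssignment:
    """A clustering of samples into k classes with the k-scan evidence."""

    sample_ids: list
    labels: np.ndarray
    k: int
    medoid_ids: list
    ch_by_k: dict = field(default_factory=dict)
    local_maxima: list = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=pd.Index(self.sample_ids,
                                                     name="sample_id"),
                         name="class")

    def to_tsv(self, path) -> None:
        self.as_series().to_csv(path, sep="\t")


class PAM(ClusterMixin, BaseEstimator):
    """Partition Around Medoids on a precomputed dissimilarity matrix.

    Deterministic greedy BUILD seeding followed by full SWAP iterated to a
    local optimum (ties broken by lowest medoid position, then lowest
    candidate index).  ``random_state`` only matters when ``n_restarts`` > 0,
    in which case additional random initial medoid sets are tried and the
    lowest-cost local optimum is kept.

    Attributes (after ``fit``): ``medoid_indices_``, ``labels_``,
    ``inertia_`` (total within-class dissimilarity to medoids),
    ``build_inertia_``, ``n_iter_``.
    """

    def __init__(self, n_clusters: int = 2, max_iter: int = 300,
                 n_restarts: int = 0, random_state=None,
                 exact_limit: int = 2048):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.exact_limit = exact_limit

    # -- internals -------------------------------------------------------
    @staticmethod
    def _build(d: np.ndarray, k: int) -> np.ndarray:
        n = d.shape[0]
        medoids = np.empty(k, dtype=np.intp)
        medoids[0] = int(np.argmin(d.sum(axis=1)))
        dn = d[medoids[0]].copy()
        chosen = np.zeros(n, dtype=bool)
        chosen[medoids[0]] = True
        for j in range(1, k):
            gains = np.maximum(dn[None, :] - d, 0.0).sum(axis=1)
            gains[chosen] = -np.inf
            nxt = int(np.argmax(gains))
            medoids[j] = nxt
            chosen[nxt] = True
            np.minimum(dn, d[nxt], out=dn)
        return medoids

    def _swap(self, d: np.ndarray, medoids: np.ndarray) -> tuple:
        n = d.shape[0]
        k = medoids.size
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            dmat = d[medoids]  # k x n
            order = np.argsort(dmat, axis=0, kind="stable")
            nearest = order[0]
            dn = dmat[nearest, np.arange(n)]
            ds = dmat[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
            best = (0.0, -1, -1)
            in_set = np.zeros(n, dtype=bool)
            in_set[medoids] = True
            for h in range(n):
                if in_set[h]:
                    continue
                d_h = d[h]
                b = np.minimum(d_h - dn, 0.0)
                total_b = b.sum()
                a = np.bincount(nearest,
                                weights=np.minimum(d_h, ds) - dn,
                                minlength=k)
                c = np.bincount(nearest, weights=b, minlength=k)
                delta = a + (total_b - c)
                j = int(np.argmin(delta))
                if delta[j] < best[0] - 1e-12:
                    best = (float(delta[j]), j, h)
                elif abs(delta[j] - best[0]) <= 1e-12 and best[1] >= 0:
                    # deterministic tie-break: keep earlier (j, h)
                    pass
            if best[1] < 0:
                break
            medoids = medoids.copy()
            medoids[best[1]] = best[2]
        dmat = d[medoids]
        labels = np.argmin(dmat, axis=0)
        cost = float(dmat[labels, np.arange(n)].sum())
        return medoids, labels, cost, n_iter

    @staticmethod
    def _exact(d: np.ndarray, k: int) -> tuple:
        n = d.shape[0]
        best = (np.inf, None)
        for subset in itertools.combinations(range(n), k):
            c = d[list(subset)].min(axis=0).sum()
            if c < best[0] - 1e-12:  # lexicographically first optimum kept
                best = (c, subset)
        medoids = np.asarray(best[1], dtype=np.intp)
        dmat = d[medoids]
        labels = np.argmin(dmat, axis=0)
        return medoids, labels, float(best[0]), 0

    def fit(self, X, y=None):
        d, ids = _as_square(X)
        n = d.shape[0]
        k = int(self.n_clusters)
        if not 2 <= k < n:
            raise ValueError(f"n_clusters must satisfy 2 <= k < n (k={k}, n={n})")
        medoids0 = self._build(d, k)
        dmat = d[medoids0]
        self.build_inertia_ = float(
            dmat[np.argmin(dmat, axis=0), np.arange(n)].sum())
        if _comb(n, k) <= self.exact_limit:
            # tiny instances: enumerate every medoid subset (global optimum)
            medoids, labels, cost, n_iter = self._exact(d, k)
        else:
            medoids, labels, cost, n_iter = self._swap(d, medoids0)
        if self.n_restarts:
            rng = np.random.default_rng(self.random_state)
            for _ in range(self.n_restarts):
                start = rng.choice(n, size=k, replace=False)
                cand = self._swap(d, np.asarray(start, dtype=np.intp))
                if cand[2] < cost - 1e-12:
                    medoids, labels, cost, n_iter = cand
        # canonical order: medoids sorted by index, labels re-coded to match
        order = np.argsort(medoids)
        remap = np.empty(k, dtype=np.intp)
        remap[order] = np.arange(k)
        self.medoid_indices_ = medoids[order]
        self.labels_ = remap[labels]
        self.inertia_ = cost
        self.n_iter_ = n_iter
        self.sample_ids_ = ids
        return self

    def to_assignment(self) -> ClassAssignment:
        return ClassAssignment(self.sample_ids_, self.labels_.copy(),
                               int(self.n_clusters),
                               [self.sample_ids_[i]
                                for i in self.medoid_indices_])


def ch_index(x, labels, is_distance: bool | None = None) -> float:
    """Calinski-Harabasz index of a labelling.

    ``x`` is either a coordinate matrix or a square dissimilarity matrix; in
    the latter case coordinates are obtained by PCoA (all positive axes),
    keeping the CH computation consistent with the clustering input.
    """
    labels = np.asarray(list(labels))
    if isinstance(x, DistanceMatrix):
        mat, is_distance = x.data, True
    else:
        mat = np.asarray(x, dtype=float)
    if is_distance is None:
        is_distance = (mat.ndim == 2 and mat.shape[0] == mat.shape[1]
                       and np.allclose(mat, mat.T)
                       and np.allclose(np.diag(mat), 0))
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("CH requires at least two classes")
    if np.any(counts == 0) or labels.size <= uniq.size:
        raise ValueError("every class must be non-empty and n > k")
    coords = pcoa(mat).coordinates if is_distance else mat
    return float(calinski_harabasz_score(coords, labels))


class CommunityTyper(ClusterMixin, BaseEstimator):
    """k-scan community typing: PAM per k, CH selection of k_opt.

    Runs PAM for every k in [k_min, k_max], computes CH in PCoA space,
    records the CH curve, its global argmax (k_opt) and all interior local
    maxima.  ``pin_k`` overrides the selection without hiding the evidence.

    Attributes: ``labels_``, ``k_opt_``, ``k_used_``, ``ch_by_k_``,
    ``local_maxima_``, ``medoid_indices_``, ``results_`` (per-k PAM output).
    """

    def __init__(self, k_min: int = 2, k_max: int | None = None,
                 pin_k: int | None = None, n_restarts: int = 0,
                 random_state=None):
        self.k_min = k_min
        self.k_max = k_max
        self.pin_k = pin_k
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        d, ids = _as_square(X)
        n = d.shape[0]
        k_max = self.k_max if self.k_max is not None else min(25, n - 1)
        if not 2 <= self.k_min <= k_max < n:
            raise ValueError(
                f"need 2 <= k_min <= k_max < n (got {self.k_min}, {k_max}, {n})")
        coords = pcoa(d).coordinates
        self.results_ = {}
        self.ch_by_k_ = {}
        for k in range(self.k_min, k_max + 1):
            est = PAM(n_clusters=k, n_restarts=self.n_restarts,
                      random_state=self.random_state).fit(d)
            self.results_[k] = est
            self.ch_by_k_[k] = float(
                calinski_harabasz_score(coords, est.labels_))
        ks = sorted(self.ch_by_k_)
        ch = np.array([self.ch_by_k_[k] for k in ks])
        self.k_opt_ = int(ks[int(np.argmax(ch))])
        self.local_maxima_ = [
            ks[i] for i in range(1, len(ks) - 1)
            if ch[i] > ch[i - 1] and ch[i] > ch[i + 1]
        ]
        self.k_used_ = int(self.pin_k) if self.pin_k is not None else self.k_opt_
        if self.k_used_ not in self.results_:
            raise ValueError(f"pinned k={self.k_used_} outside scanned range")
        best = self.results_[self.k_used_]
        self.labels_ = best.labels_
        self.medoid_indices_ = best.medoid_indices_
        self.sample_ids_ = ids
        return self

    def to_assignment(self, k: int | None = None) -> ClassAssignment:
        k = self.k_used_ if k is None else int(k)
        est = self.results_[k]
        return ClassAssignment(self.sample_ids_, est.labels_.copy(), k,
                               [self.sample_ids_[i]
                                for i in est.medoid_indices_],
                               dict(self.ch_by_k_), list(self.local_maxima_))


# -- thin functional wrappers ------------------------------------------------

def pam(d, k: int, seed=None) -> ClassAssignment:
    return PAM(n_clusters=k, random_state=seed).fit(d).to_assignment()


def scan_k(d, k_min: int = 2, k_max: int | None = None, seed=None,
           pin_k: int | None = None) -> ClassAssignment:
    return CommunityTyper(k_min=k_min, k_max=k_max, pin_k=pin_k,
                          random_state=seed).fit(d).to_assignment()
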