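"""Jensen-Shannon dissimilarities, principal coordinates and ANOSIM.

Community comparisons throughout the package are based on the Jensen-Shannon
divergence between relative-abundance compositions,

    JSD(p, q) = 1/2 KL(p || m) + 1/2 KL(q || m),   m = (p + q) / 2,

with the 0 log 0 = 0 convention so zero-abundance ASVs need no pseudocounts.
In base 2 the divergence is bounded by 1 and its square root is a metric,
which is what clustering and ordination consume.  Group separation on a
dissimilarity matrix is measured with the rank-based ANOSIM R statistic and
assessed by label permutation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import rel_entr, xlogy
from scipy.stats import rankdata
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)

_LOG_BASE = {2: np.log(2.0), "e": 1.0, np.e: 1.0}


def _base_factor(base) -> float:
    try:
        return _LOG_BASE[base]
    except (KeyError, TypeError):
        raise ValueError(f"log base must be 2 or 'e', got {base!r}") from None


def _as_abund(t) -> tuple[np.ndarray, list]:
    """Accept a RelAbundTable, DataFrame or ndarray of compositions."""
    if hasattr(t, "abund"):
        return t.abund, t.sample_ids
    if isinstance(t, pd.DataFrame):
        return t.to_numpy(dtype=float), list(t.index)
    arr = np.asarray(t, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def jsd_pair(p, q, base=2) -> float:
    """Jensen-Shannon divergence between two probability vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < 0):
            raise ValueError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} does not sum to 1 (sum={v.sum():.12f})")
    m = 0.5 * (p + q)
    div = 0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()
    return float(max(div, 0.0)) / _base_factor(base)


def jsd_matrix(t, base=2, as_distance: bool = True) -> DistanceMatrix:
    """All-against-all Jensen-Shannon dissimilarity of a composition table.

    With ``as_distance`` (default) the square root of each divergence is
    returned, which is a metric suitable for clustering and ordination.
    """
    x, ids = _as_abund(t)
    if np.any(x < 0):
        raise ValueError("compositions must be non-negative")
    sums = x.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ValueError("every row must sum to 1")
    n = x.shape[0]
    # JSD(p,q) = H(m) - (H(p)+H(q))/2 with H in nats, rescaled afterwards
    h = -xlogy(x, x).sum(axis=1)
    d = np.zeros((n, n))
    for i in range(n - 1):
        m = 0.5 * (x[i] + x[i + 1:])
        hm = -xlogy(m, m).sum(axis=1)
        d[i, i + 1:] = hm - 0.5 * (h[i] + h[i + 1:])
    d = (d + d.T) / _base_factor(base)
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0
    if as_distance:
        d = np.sqrt(d)
    return DistanceMatrix(d, ids=[str(i) for i in ids])


# ---------------------------------------------------------------------------
# Principal coordinates (classical metric scaling)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinationResult:
    """PCoA embedding: axes ordered by decreasing (positive) eigenvalue."""

    sample_ids: list
    coordinates: np.ndarray  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray
    negative_inertia: float = 0.0  # |sum of negative eigenvalues| / sum |all|


def pcoa(d, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric scaling of a dissimilarity matrix.

    Double-centres -d^2/2, eigendecomposes, and keeps only axes with
    positive eigenvalues (no Cailliez correction); the discarded negative
    inertia fraction is recorded on the result.
    """
    if isinstance(d, DistanceMatrix):
        ids, mat = list(d.ids), d.data
    else:
        mat = np.asarray(d, dtype=float)
        ids = [str(i) for i in range(mat.shape[0])]
    n = mat.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (mat ** 2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-12 if n else 0.0
    pos = vals > tol
    total = np.abs(vals).sum()
    neg_frac = float(np.abs(vals[vals < -tol]).sum() / total) if total else 0.0
    if neg_frac:
        logger.info("PCoA dropped %.1f%% negative inertia", 100 * neg_frac)
    vals_pos, vecs_pos = vals[pos], vecs[:, pos]
    coords = vecs_pos * np.sqrt(vals_pos)
    if n_axes is not None:
        if n_axes > coords.shape[1]:
            warnings.warn(
                f"requested {n_axes} axes but only {coords.shape[1]} have "
                "positive eigenvalues; truncating", stacklevel=2)
        coords = coords[:, :n_axes]
        vals_pos = vals_pos[:n_axes]
    return OrdinationResult(ids, coords, vals_pos, neg_frac)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnosimResult:
    """ANOSIM R with its permutation p-value.

    R contrasts mean between- and within-group ranks of the off-diagonal
    dissimilarities; 0 for random groupings, 1 for complete separation.
    """

    r: float
    n_groups: int
    n_permutations: int
    p_value: float
    permuted_r: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.n_permutations > 0 and not (
                self.p_value >= 1.0 / (self.n_permutations + 1)):
            raise ValueError("p-value below the add-one permutation floor")


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    # ranks/within are condensed (upper-triangle) vectors
    n_pairs = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    # Clarke's denominator: n(n-1)/4 == (number of pairs)/2
    return (rb - rw) / (n_pairs / 2.0)


def anosim(d, groups, n_perm: int = 1000, seed: int | None = None
           ) -> AnosimResult:
    """ANOSIM with average-rank ties and an add-one permutation p-value.

    ``groups`` is a label per sample (aligned with the matrix ids when a
    skbio DistanceMatrix is given).
    """
    if isinstance(d, DistanceMatrix):
        mat = d.data
    else:
        mat = np.asarray(d, dtype=float)
    labels = np.asarray(list(groups))
    n = mat.shape[0]
    if labels.shape[0] != n:
        raise ValueError("one group label per sample is required")
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM requires at least two groups")
    if uniq.size >= n:
        raise ValueError("every sample in its own group is degenerate")
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(mat[iu, ju])
    within = codes[iu] == codes[ju]
    r_obs = _anosim_r(ranks, within)

    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(codes)
        permuted[b] = _anosim_r(ranks, perm[iu] == perm[ju])
    p = (np.count_nonzero(permuted >= r_obs) + 1) / (n_perm + 1)
    return AnosimResult(float(r_obs), int(uniq.size), int(n_perm), float(p),
                        permuted)


def write_dissimilarity(d: DistanceMatrix, path) -> None:
    pd.DataFrame(d.data, index=list(d.ids), columns=list(d.ids)).to_csv(
        path, sep="\t")


def read_dissimilarity(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])
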