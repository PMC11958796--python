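"""Rigid-body superposition of paired community composition matrices.

Can the final compositions be obtained from the starting compositions by a
translation plus rotation in ASV space?  The optimal such transformation is
found with the Kabsch algorithm: centre both matrices on their column means,
take the SVD of the cross-covariance Xc'Yc = U S V' and rotate with
R = U D V', where D corrects an improper (reflecting) solution so that only
rigid motions are allowed.  The quality of the fit is the RMSD (root mean
squared row-wise Euclidean deviation); its null distribution is obtained by
refitting after shuffling every cell of the starting matrix.  Prediction
quality against held-out replicates is assessed by correlating the leading
SVD score components of the transformed start matrix with those of each
holdout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .dissimilarity import _as_abund


class RigidSuperposition(BaseEstimator):
    """Kabsch fit of a translation + rotation mapping X rows onto Y rows.

    Row i of X must be paired with row i of Y (same parent community) and
    both matrices must share their ASV columns.  With p columns and n rows,
    a dense p x p rotation is materialised only when ``p <= dense_limit``;
    otherwise thin factors are kept and only the rotation's action on the
    data span is ever computed (for p > n the reflection correction lives in
    the null space of the cross-covariance and does not affect the fit).

    Attributes: ``rmsd_``, ``x_mean_``, ``y_mean_``, ``singular_values_``,
    ``rotation_`` (dense mode only).
    """

    def __init__(self, dense_limit: int = 512):
        self.dense_limit = dense_limit

    def fit(self, X, Y):
        x, _ = _as_abund(X)
        y, _ = _as_abund(Y)
        if x.shape != y.shape:
            raise ValueError(f"paired matrices must match: {x.shape} vs {y.shape}")
        n, p = x.shape
        if n < 3:
            raise ValueError("at least 3 paired samples are required")
        self.x_mean_ = x.mean(axis=0)
        self.y_mean_ = y.mean(axis=0)
        xc = x - self.x_mean_
        yc = y - self.y_mean_
        if p <= self.dense_limit:
            u, s, vt = np.linalg.svd(xc.T @ yc)
            sign = np.sign(np.linalg.det(u @ vt)) or 1.0
            self._signs = np.ones(p)
            self._signs[-1] = sign
            self._u, self._vt = u, vt
            self.singular_values_ = s
            self._dense = True
        else:
            # economy route: rank(Xc'Yc) <= n << p, so work in the data span
            qx, rx = np.linalg.qr(xc.T)
            qy, ry = np.linalg.qr(yc.T)
            u, s, vt = np.linalg.svd(rx @ ry.T)
            self._u = qx @ u
            self._vt = vt @ qy.T
            # determinant is fixed up in the (fit-irrelevant) null space
            self._signs = np.ones(self._u.shape[1])
            self.singular_values_ = s
            self._dense = False
        self.n_samples_, self.n_features_ = n, p
        self.rmsd_ = float(
            np.linalg.norm(self._apply_centred(xc) - yc) / np.sqrt(n))
        return self

    def _apply_centred(self, xc: np.ndarray) -> np.ndarray:
        return ((xc @ self._u) * self._signs) @ self._vt

    def predict(self, X) -> np.ndarray:
        """Apply the fitted rigid motion to new rows in the same ASV space."""
        x, _ = _as_abund(X)
        return self._apply_centred(x - self.x_mean_) + self.y_mean_

    transform = predict

    @property
    def rotation_(self) -> np.ndarray:
        if not self._dense:
            raise AttributeError(
                "rotation matrix not materialised in economy mode; "
                "use predict/transform for its action")
        return (self._u * self._signs) @ self._vt

    @property
    def translation_(self) -> np.ndarray:
        """Offset mapping the rotated, centred X onto Y's frame."""
        return self.y_mean_ - self.x_mean_


def kabsch_fit(x, y, dense_limit: int = 512) -> RigidSuperposition:
    """Fit the optimal rigid motion of x onto y (see RigidSuperposition)."""
    return RigidSuperposition(dense_limit=dense_limit).fit(x, y)


def randomised_rmsd_ci(x, y, n_rand: int = 50, seed=None,
                       return_null: bool = False):
    """Null RMSD interval from cell-shuffled starting matrices.

    Each randomisation flattens x, permutes all cells, reshapes, and refits
    against the unmodified y; the 2.5/97.5 percentiles of the null RMSDs are
    returned (optionally with the full null sample).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    xa, _ = _as_abund(x)
    rng = np.random.default_rng(seed)
    null = np.empty(n_rand)
    for b in range(n_rand):
        shuffled = rng.permutation(xa.ravel()).reshape(xa.shape)
        null[b] = kabsch_fit(shuffled, y).rmsd_
    if n_rand == 1:
        warnings.warn("single randomisation gives a degenerate CI",
                      stacklevel=2)
        lo = hi = float(null[0])
    else:
        lo, hi = np.percentile(null, [2.5, 97.5])
    if return_null:
        return (float(lo), float(hi)), null
    return float(lo), float(hi)


@dataclass(frozen=True)
class ComponentComparison:
    """Per-holdout, per-SVD-component linear agreement with the prediction."""

    replicate_id: str
    component_index: int  # 1-based
    r_squared: float
    p_value: float
    slope: float
    intercept: float


def svd_scores(mat: np.ndarray, center: bool = True) -> np.ndarray:
    """Thin SVD sample scores (left singular vectors times singular values)."""
    m = np.asarray(mat, dtype=float)
    if center:
        m = m - m.mean(axis=0)
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    return u * s


def predict_and_compare(x, fit: RigidSuperposition, holdouts,
                        components=(1, 2), center: bool = True
                        ) -> list[ComponentComparison]:
    """Compare SVD components of the transformed start matrix to holdouts.

    Signs of the holdout components are aligned so the paired Pearson
    correlation is non-negative (component signs are arbitrary); R-squared is
    unaffected by this choice.
    """
    pred = fit.predict(x)
    if pred.shape[0] < 3:
        raise ValueError("at least 3 paired samples are required")
    sp = svd_scores(pred, center=center)
    if isinstance(holdouts, dict):
        items = list(holdouts.items())
    else:
        items = [(str(i + 1), h) for i, h in enumerate(holdouts)]
    out = []
    for rep_id, h in items:
        ha, _ = _as_abund(h)
        if ha.shape != pred.shape:
            raise ValueError(f"holdout {rep_id} shape mismatch")
        sh = svd_scores(ha, center=center)
        for ci in components:
            a, b = sp[:, ci - 1], sh[:, ci - 1]
            if np.corrcoef(a, b)[0, 1] < 0:
                b = -b
            lr = stats.linregress(a, b)
            out.append(ComponentComparison(
                replicate_id=str(rep_id), component_index=int(ci),
                r_squared=float(lr.rvalue ** 2), p_value=float(lr.pvalue),
                slope=float(lr.slope), intercept=float(lr.intercept)))
    return out
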