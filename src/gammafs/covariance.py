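"""Covariance estimation for class ellipsoids.

Two estimators are used throughout the package:

* the empirical covariance with the unbiased ``n - 1`` denominator, and
* the Schäfer–Strimmer shrinkage estimator, which shrinks the sample
  correlations toward zero and the sample variances toward their median,
  each with an analytic (data-driven) shrinkage intensity.

Shrinkage guarantees a positive-definite estimate whenever the correlation
intensity is positive, which is what makes class-separability scores usable
when a class has fewer observations than features.
"""

from __future__ import annotations

import numpy as np

__all__ = ["empirical_covariance", "shrinkage_covariance", "ShrinkagePrecompute"]


def empirical_covariance(X: np.ndarray) -> np.ndarray:
    """Unbiased sample covariance of the rows of ``X`` (denominator ``n - 1``)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations for a covariance")
    return np.atleast_2d(np.cov(X, rowvar=False))


def _variance_shrinkage(v: np.ndarray, var_v: np.ndarray) -> tuple[np.ndarray, float]:
    """Shrink variances toward their median with analytic intensity."""
    target = np.median(v)
    denom = float(((v - target) ** 2).sum())
    lam = 1.0 if denom == 0.0 else min(1.0, max(0.0, float(var_v.sum()) / denom))
    return lam * target + (1.0 - lam) * v, lam


def _correlation_intensity(sum_var_r_off: float, sum_r2_off: float) -> float:
    if sum_r2_off <= 0.0:
        return 1.0
    return min(1.0, max(0.0, sum_var_r_off / sum_r2_off))


def shrinkage_covariance(X: np.ndarray, return_intensities: bool = False):
    """Schäfer–Strimmer shrinkage covariance of the rows of ``X``.

    The correlation matrix is shrunk toward the identity with intensity
    ``lambda* = sum Var(r_ij) / sum r_ij^2`` over off-diagonal entries, and
    the variances toward their median with the analogous ratio; both
    intensities are clipped to ``[0, 1]``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations for a covariance")
    pre = ShrinkagePrecompute(X)
    cov, lam, lam_var = pre.covariance(np.arange(p))
    if return_intensities:
        return cov, lam, lam_var
    return cov


class ShrinkagePrecompute:
    """Per-column/per-pair statistics enabling O(d^2) shrinkage on any subset.

    The shrinkage intensity for a feature subset depends only on pairwise
    statistics of the columns in the subset, so the full ``p x p`` tables are
    computed once and subsets are served from slices.  This is exact: the
    result is identical to running the estimator on ``X[:, subset]``.
    """

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 observations")
        self.n = n
        xc = X - X.mean(axis=0)
        self.v = (xc ** 2).sum(axis=0) / (n - 1)          # unbiased variances
        z = xc ** 2
        self.var_v = n / (n - 1) ** 3 * ((z - z.mean(axis=0)) ** 2).sum(axis=0)
        sd = np.sqrt(np.where(self.v > 0, self.v, 1.0))
        xs = xc / sd
        wbar = (xs.T @ xs) / n
        self.r = n / (n - 1) * wbar                        # sample correlations
        # Var(r_ij) from the centered products w_kij = xs_ki * xs_kj:
        # sum_k (w_kij - wbar_ij)^2 = sum_k w_kij^2 - n wbar_ij^2
        s2 = (xs ** 2).T @ (xs ** 2)
        self.var_r = n / (n - 1) ** 3 * (s2 - n * wbar ** 2)
        self._r2 = self.r ** 2

    def covariance(self, subset) -> tuple[np.ndarray, float, float]:
        """Shrinkage covariance on ``subset`` with its two intensities."""
        idx = np.asarray(list(subset), dtype=int)
        d = idx.size
        v_s = self.v[idx]
        vs, lam_var = _variance_shrinkage(v_s, self.var_v[idx])
        if d == 1:
            return np.array([[vs[0]]]), 0.0, lam_var
        r_s = self.r[np.ix_(idx, idx)]
        var_r_s = self.var_r[np.ix_(idx, idx)]
        off = ~np.eye(d, dtype=bool)
        lam = _correlation_intensity(float(var_r_s[off].sum()),
                                     float(self._r2[np.ix_(idx, idx)][off].sum()))
        rs = (1.0 - lam) * r_s
        np.fill_diagonal(rs, 1.0)
        sds = np.sqrt(vs)
        return rs * np.outer(sds, sds), lam, lam_var
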