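"""Vectorised (multi-response) weighted least squares with robust errors.

Shared fitting engine: one design matrix, optionally many response columns,
optional observation weights, sandwich (HC0) or naive standard errors.
Used by the propensity, screening and mediation-test stages; kept free of
statsmodels so thousands of small fits per replication stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["WLSResult", "wls_fit"]


@dataclass
class WLSResult:
    """Coefficients and inference for each response column.

    All arrays have shape (n_coef,) for a single response or
    (n_coef, n_responses) for a stacked multi-response fit.
    """

    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    resid: np.ndarray
    df_resid: int


def _check_rank(Z: np.ndarray, names=None) -> None:
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for j in range(Z.shape[1]):
            keep = [c for c in range(Z.shape[1]) if c != j]
            if np.linalg.matrix_rank(Z[:, keep]) == rank:
                bad.append(names[j] if names is not None else j)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def wls_fit(
    Z: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    robust: bool = True,
    column_names=None,
) -> WLSResult:
    """Weighted least squares of ``y`` (1-D or n x k) on design ``Z``.

    Minimises sum_i w_i (y_i - Z_i b)^2.  ``robust=True`` returns
    heteroskedasticity-robust (HC0 sandwich) standard errors with normal
    p-values — appropriate when the weights are balancing weights rather
    than precision weights; ``robust=False`` returns naive WLS errors with
    t p-values.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = y[:, None] if single else y
    n, k = Z.shape
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape[0] != n:
            raise ValueError("weights length does not match design rows")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
    _check_rank(Z, column_names)

    Zw = Z * w[:, None]
    A = Z.T @ Zw                       # Z' W Z
    Ainv = np.linalg.inv(A)
    params = Ainv @ (Zw.T @ Y)         # (k, m)
    resid = Y - Z @ params
    df = n - k
    if robust:
        # B = Z' diag(w^2 e^2) Z, one per response column
        we2 = (w[:, None] ** 2) * resid**2            # (n, m)
        B = np.einsum("nj,nm,nk->mjk", Z, we2, Z)     # (m, k, k)
        cov = Ainv @ B @ Ainv
        bse = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2).T, 0.0))
        zstat = np.divide(params, bse, out=np.zeros_like(params), where=bse > 0)
        pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    else:
        sigma2 = np.einsum("nm,nm->m", w[:, None] * resid, resid) / max(df, 1)
        bse = np.sqrt(np.outer(np.diag(Ainv), sigma2))
        tstat = np.divide(params, bse, out=np.zeros_like(params), where=bse > 0)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), max(df, 1))
    if single:
        return WLSResult(params[:, 0], bse[:, 0], pvals[:, 0], resid[:, 0], df)
    return WLSResult(params, bse, pvals, resid, df)
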