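"""Confounding-controlled sure independence screening (SIS).

Reduces the p mediators to d = floor(2n / log n) candidates ranked by the
magnitude of the adjusted mediator->outcome effect |beta_k|.  Under the
weighting schemes (IPW/OW) each beta_k is estimated by a two-step
procedure: a weighted fit of the outcome on (1, X, M_k) gives the adjusted
exposure coefficient, whose contribution is removed from the outcome before
an unweighted simple regression on M_k.  Under RA/PSR, beta_k comes from an
ordinary fit with the confounders (or the propensity score) as covariates.

Ranking by |alpha_k beta_k| is available (``basis="alpha_beta"``) for
fidelity to earlier two-stage procedures but is not the default: with
confounding, the product statistic is a markedly less reliable screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._wls import wls_fit
from .datasets import MediationDataset
from .propensity import ADJUSTMENTS, PropensityFit, WeightVector, compute_weights, fit_propensity

__all__ = ["ScreenResult", "sis_dimension", "two_step_beta", "screen_mediators"]


@dataclass
class ScreenResult:
    """Per-mediator screening statistics and the retained index set."""

    statistic: np.ndarray
    kept: np.ndarray
    d: int
    method: str
    basis: str

    # full per-mediator estimates behind the statistic (for reporting)
    beta_hat: np.ndarray | None = None
    beta_se: np.ndarray | None = None
    beta_p: np.ndarray | None = None


def sis_dimension(n: int) -> int:
    """Screening target dimension d = floor(2n / log n) (natural log)."""
    if n < 3:
        raise ValueError(f"n must be >= 3 for the SIS dimension, got {n}")
    return int(math.floor(2.0 * n / math.log(n)))


def two_step_beta(
    Y: np.ndarray,
    X: np.ndarray,
    M_k: np.ndarray,
    weights: np.ndarray | WeightVector,
):
    """Two-step weighted estimate of a single mediator's outcome effect.

    Step 1 fits Y ~ 1 + X + M_k by weighted least squares and keeps the
    exposure coefficient gamma_hat; step 2 regresses the exposure-adjusted
    outcome Y - gamma_hat*X on (1, M_k) without weights.  Returns
    ``(beta_hat, se, p_value)`` from step 2.
    """
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights)
    Y = np.asarray(Y, dtype=float).ravel()
    X = np.asarray(X, dtype=float).ravel()
    M_k = np.asarray(M_k, dtype=float).ravel()
    if np.ptp(M_k) == 0.0:
        raise ValueError("mediator column is constant; degenerate regressor")
    n = Y.shape[0]
    step1 = wls_fit(np.column_stack([np.ones(n), X, M_k]), Y, weights=w)
    gamma_hat = step1.params[1]
    e_hat = Y - gamma_hat * X
    step2 = wls_fit(np.column_stack([np.ones(n), M_k]), e_hat, robust=False)
    return step2.params[1], step2.bse[1], step2.pvalues[1]


def _residualize(Z: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Residuals of each column of A after OLS on Z."""
    coef, *_ = np.linalg.lstsq(Z, A, rcond=None)
    return A - Z @ coef


def _fwl_betas(Z: np.ndarray, M: np.ndarray, Y: np.ndarray):
    """Per-column beta_k from OLS of Y on (Z, M_k), via partitioned regression.

    Returns (beta, se, p) with homoskedastic standard errors on
    n - (q_Z + 1) residual degrees of freedom.
    """
    rM = _residualize(Z, M)
    rY = _residualize(Z, Y[:, None])[:, 0]
    smm = np.einsum("nk,nk->k", rM, rM)
    if np.any(smm <= 0):
        raise ValueError("constant (or Z-collinear) mediator column encountered")
    beta = (rM.T @ rY) / smm
    df = Y.shape[0] - Z.shape[1] - 1
    rss = np.einsum("n,n->", rY, rY) - beta**2 * smm
    rss = np.maximum(rY @ rY - beta**2 * smm, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / smm)
    tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return beta, se, p


def _two_step_betas(Y, X, M, w):
    """Vectorised two-step weighted beta_k for every mediator column."""
    n, p = M.shape
    sw = w.sum()
    swx = w @ X                      # X binary: also sum w x^2
    swy = w @ Y
    swxy = (w * X) @ Y
    swm = w @ M                      # (p,)
    swxm = (w * X) @ M
    swym = (w * Y) @ M
    swmm = np.einsum("n,nk,nk->k", w, M, M)

    A = np.empty((p, 3, 3))
    A[:, 0, 0] = sw
    A[:, 0, 1] = A[:, 1, 0] = swx
    A[:, 1, 1] = swx
    A[:, 0, 2] = A[:, 2, 0] = swm
    A[:, 1, 2] = A[:, 2, 1] = swxm
    A[:, 2, 2] = swmm
    b = np.empty((p, 3))
    b[:, 0] = swy
    b[:, 1] = swxy
    b[:, 2] = swym
    gamma = np.linalg.solve(A, b[:, :, None])[:, 1, 0]   # exposure coef per k

    # step 2: unweighted simple regression of (Y - gamma_k X) on M_k,
    # assembled from moments so the n x p residual matrix is never formed
    sx, sy = X.sum(), Y.sum()
    sm = M.sum(axis=0)
    sxx = X @ X
    sxy = X @ Y
    syy = Y @ Y
    smy = M.T @ Y
    smx = M.T @ X
    smm = np.einsum("nk,nk->k", M, M)

    se_sum = sy - gamma * sx                       # sum of e_k
    sme = smy - gamma * smx                        # sum m_k e_k
    see = syy - 2.0 * gamma * sxy + gamma**2 * sxx # sum e_k^2
    c_mm = smm - sm**2 / n
    c_me = sme - sm * se_sum / n
    c_ee = see - se_sum**2 / n
    if np.any(c_mm <= 0):
        raise ValueError("constant mediator column encountered")
    beta = c_me / c_mm
    df = n - 2
    rss = np.maximum(c_ee - beta**2 * c_mm, 0.0)
    se = np.sqrt(rss / df / c_mm)
    tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    return beta, se, pval


def marginal_alpha(
    dataset: MediationDataset,
    adjustment: str,
    ps_fit: PropensityFit | None = None,
    weights: WeightVector | None = None,
    columns: np.ndarray | None = None,
    robust_weighted_se: bool = True,
):
    """Adjusted exposure->mediator effect alpha_k for each mediator column.

    RA: OLS of M_k on (1, X, C); PSR: OLS of M_k on (1, X, PS); IPW/OW:
    weighted fit of M_k on (1, X, C) with sandwich standard errors by
    default.  Returns (alpha_hat, se, p) over ``columns`` (default: all).
    """
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"unknown adjustment {adjustment!r}; choose from {ADJUSTMENTS}")
    M = dataset.M if columns is None else dataset.M[:, columns]
    n = dataset.n
    one = np.ones(n)
    if adjustment == "ra":
        Z, w, robust = np.column_stack([one, dataset.X, dataset.C]), None, False
    elif adjustment == "psr":
        if ps_fit is None:
            ps_fit = fit_propensity(dataset.C, dataset.X)
        Z, w, robust = np.column_stack([one, dataset.X, ps_fit.scores]), None, False
    else:
        if weights is None:
            if ps_fit is None:
                ps_fit = fit_propensity(dataset.C, dataset.X)
            weights = compute_weights(ps_fit, dataset.X, adjustment)
        Z = np.column_stack([one, dataset.X, dataset.C])
        w, robust = weights.weights, robust_weighted_se
    res = wls_fit(Z, M, weights=w, robust=robust)
    return res.params[1], res.bse[1], res.pvalues[1]


def screen_mediators(
    dataset: MediationDataset,
    adjustment: str = "ow",
    basis: str = "beta",
    d: int | None = None,
    ps_fit: PropensityFit | None = None,
    weights: WeightVector | None = None,
) -> ScreenResult:
    """Rank all mediators by the adjusted |beta_k| (or |alpha_k beta_k|)
    and retain the top d = floor(2n/log n).

    Ties are broken by ascending mediator index for cross-platform
    determinism.
    """
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"unknown adjustment {adjustment!r}; choose from {ADJUSTMENTS}")
    if basis not in ("beta", "alpha_beta"):
        raise ValueError(f"unknown screening basis {basis!r}")
    dataset.require_both_groups()
    n, p = dataset.n, dataset.p
    d_target = sis_dimension(n) if d is None else int(d)
    d_eff = min(d_target, p)

    one = np.ones(n)
    if adjustment in ("ipw", "ow"):
        if weights is None:
            if ps_fit is None:
                ps_fit = fit_propensity(dataset.C, dataset.X)
            weights = compute_weights(ps_fit, dataset.X, adjustment)
        beta, se, pval = _two_step_betas(
            dataset.Y, dataset.X, dataset.M, weights.weights
        )
    elif adjustment == "ra":
        Z = np.column_stack([one, dataset.X, dataset.C])
        beta, se, pval = _fwl_betas(Z, dataset.M, dataset.Y)
    else:  # psr
        if ps_fit is None:
            ps_fit = fit_propensity(dataset.C, dataset.X)
        Z = np.column_stack([one, dataset.X, ps_fit.scores])
        beta, se, pval = _fwl_betas(Z, dataset.M, dataset.Y)

    statistic = np.abs(beta)
    if basis == "alpha_beta":
        alpha_hat, _, _ = marginal_alpha(dataset, adjustment, ps_fit, weights)
        statistic = statistic * np.abs(alpha_hat)
    if not np.isfinite(statistic).all():
        raise ValueError("non-finite screening statistic encountered")

    order = np.lexsort((np.arange(p), -statistic))
    kept = order[:d_eff]
    return ScreenResult(
        statistic=statistic,
        kept=kept,
        d=d_eff,
        method=adjustment,
        basis=basis,
        beta_hat=beta,
        beta_se=se,
        beta_p=pval,
    )
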