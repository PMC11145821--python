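"""Second-stage estimation on the screened candidates.

Two routes operate on the d mediators surviving the screen:

* **MCP selection** — minimax-concave-penalized least squares of the
  outcome on (X, screened mediators, covariates), exposure and covariates
  unpenalized, regularization chosen by BIC (default) or AIC over a
  log-spaced grid.  MCP applies firm thresholding: small coefficients are
  set exactly to zero while large ones are left nearly unbiased.

* **De-biased Lasso inference** — an initial cross-validated Lasso fit is
  corrected with a nodewise-regression estimate of the precision matrix,
  giving asymptotically normal per-coefficient estimates, standard errors
  and two-sided p-values p_k = 2{1 - Phi(|b_k|/s_k)}.

Both accept optional observation weights (sqrt-weight row scaling of the
least-squares loss); the default pipeline fits them unweighted with the
confounders as unpenalized covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._solvers import cd_lasso_node, cd_penalized_gram, mcp_penalty_value

__all__ = ["MCPFit", "DebiasedFit", "mcp_penalty", "fit_mcp", "fit_debiased_lasso"]


@dataclass
class MCPFit:
    """MCP-penalized fit on the screened design (original scale)."""

    coefficients: np.ndarray        # mediator-block coefficients, length d
    selected: np.ndarray            # indices into the mediator block
    lam: float
    delta: float
    criterion: str
    gamma_hat: float                # exposure coefficient
    intercept: float
    covariate_coef: np.ndarray
    criterion_path: np.ndarray = field(default=None, repr=False)
    lambda_grid: np.ndarray = field(default=None, repr=False)
    objective_path: np.ndarray = field(default=None, repr=False)


@dataclass
class DebiasedFit:
    """De-biased Lasso estimates for the mediator block (original scale)."""

    beta_hat: np.ndarray
    sigma_hat: np.ndarray
    p_values: np.ndarray
    gamma_hat: float
    gamma_se: float
    gamma_p: float
    lam_initial: float
    sigma_noise: float


def mcp_penalty(beta, lam: float, delta: float):
    """Evaluate the MCP penalty P_{lam,delta}(beta) (vectorised)."""
    if lam <= 0 or delta <= 0:
        raise ValueError("lambda and delta must be positive")
    b = np.asarray(beta, dtype=float)
    out = np.where(
        np.abs(b) < delta * lam,
        lam * (np.abs(b) - b**2 / (2.0 * lam * delta)),
        0.5 * lam**2 * delta,
    )
    return float(out) if np.isscalar(beta) else out


def _standardize(D: np.ndarray, y: np.ndarray, weights=None):
    """Center y, center/scale columns of D to unit variance.

    With weights, rows are pre-multiplied by sqrt(w) after weighted
    centering, so the unweighted machinery minimises the weighted loss.
    """
    n = D.shape[0]
    if weights is None:
        mu = D.mean(axis=0)
        ybar = y.mean()
        Dc = D - mu
        yc = y - ybar
        sd = Dc.std(axis=0)
    else:
        w = np.asarray(weights, dtype=float)
        wn = w / w.sum()
        mu = wn @ D
        ybar = wn @ y
        Dc = (D - mu) * np.sqrt(w * n / w.sum())[:, None]
        yc = (y - ybar) * np.sqrt(w * n / w.sum())
        sd = np.sqrt((Dc**2).mean(axis=0))
    if np.any(sd <= 0):
        raise ValueError("constant column in the penalized design")
    return Dc / sd, yc, mu, ybar, sd


def _lambda_grid(Ds, yc, penalty_factor, n_lambda=100, ratio=1e-3):
    """Log-spaced grid from lambda_max (all penalized coefs zero) down."""
    n = Ds.shape[0]
    unpen = penalty_factor == 0.0
    if unpen.any():
        coef, *_ = np.linalg.lstsq(Ds[:, unpen], yc, rcond=None)
        r0 = yc - Ds[:, unpen] @ coef
    else:
        r0 = yc
    lam_max = np.max(np.abs(Ds[:, ~unpen].T @ r0)) / n
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _path(G, c, lams, delta, penalty_factor, yty_n):
    """Solve along a descending lambda path with warm starts.

    Returns (coef path, objective values at the solution for each lambda).
    """
    P = G.shape[0]
    betas = np.empty((len(lams), P))
    objs = np.empty(len(lams))
    b = np.zeros(P)
    for i, lam in enumerate(lams):
        cd_penalized_gram(G, c, lam, delta, penalty_factor, b)
        betas[i] = b
        pen = 0.0
        if delta > 0:
            for j in np.flatnonzero(penalty_factor):
                pen += mcp_penalty_value(b[j], lam * penalty_factor[j], delta)
        else:
            pen = lam * np.abs(b[penalty_factor > 0]).sum()
        objs[i] = 0.5 * (yty_n - 2.0 * c @ b + b @ G @ b) + pen
    return betas, objs


def _assemble_design(X, M, covariates):
    X = np.asarray(X, dtype=float).ravel()
    M = np.atleast_2d(np.asarray(M, dtype=float))
    blocks = [X[:, None], M]
    ncov = 0
    if covariates is not None:
        Cv = np.asarray(covariates, dtype=float)
        if Cv.ndim == 1:
            Cv = Cv[:, None]
        blocks.append(Cv)
        ncov = Cv.shape[1]
    D = np.hstack(blocks)
    return D, M.shape[1], ncov


def fit_mcp(
    Y,
    X,
    M_screened,
    covariates=None,
    lambda_grid=None,
    delta: float = 3.0,
    criterion: str = "bic",
    weights=None,
    n_lambda: int = 100,
) -> MCPFit:
    """MCP-penalized outcome model over the screened mediators.

    The exposure and covariate columns are unpenalized; mediator
    coefficients are estimated under MCP with concavity ``delta`` and the
    regularization value chosen by ``criterion`` ('bic' or 'aic') along a
    descending grid.  Estimates are returned on the original scale.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    Y = np.asarray(Y, dtype=float).ravel()
    D, d, ncov = _assemble_design(X, M_screened, covariates)
    n, P = D.shape
    if d >= n:
        raise ValueError(
            f"screened dimension d={d} must be below n={n}; rerun the screen "
            "with a smaller d"
        )
    penalty_factor = np.zeros(P)
    penalty_factor[1 : 1 + d] = 1.0

    Ds, yc, mu, ybar, sd = _standardize(D, Y, weights)
    G = Ds.T @ Ds / n
    c = Ds.T @ yc / n
    yty_n = yc @ yc / n
    lams = (
        np.asarray(lambda_grid, dtype=float)
        if lambda_grid is not None
        else _lambda_grid(Ds, yc, penalty_factor, n_lambda)
    )
    lams = np.sort(lams)[::-1]
    betas, objs = _path(G, c, lams, delta, penalty_factor, yty_n)

    rss = n * np.maximum(yty_n - 2.0 * betas @ c + np.einsum("ij,jk,ik->i", betas, G, betas), 1e-12)
    k = (betas != 0).sum(axis=1)
    pen_term = np.log(n) if criterion == "bic" else 2.0
    score = n * np.log(rss / n) + pen_term * k
    best = int(np.argmin(score))

    b_std = betas[best]
    b_orig = b_std / sd
    intercept = ybar - mu @ b_orig
    med = b_orig[1 : 1 + d]
    return MCPFit(
        coefficients=med,
        selected=np.flatnonzero(med != 0.0),
        lam=float(lams[best]),
        delta=delta,
        criterion=criterion,
        gamma_hat=float(b_orig[0]),
        intercept=float(intercept),
        covariate_coef=b_orig[1 + d :],
        criterion_path=score,
        lambda_grid=lams,
        objective_path=objs,
    )


def _kfold_indices(n, n_folds, rng):
    idx = rng.permutation(n)
    return np.array_split(idx, n_folds)


def _cv_lasso_lambda(Ds, yc, penalty_factor, n_folds, seed, n_lambda=100,
                     ratio=1e-2):
    """Cross-validated lambda for the Lasso on the standardized design.

    Fold fits use a relaxed coordinate-descent tolerance; only the final
    refit at the chosen lambda is solved to full precision.
    """
    n = Ds.shape[0]
    lams = _lambda_grid(Ds, yc, penalty_factor, n_lambda, ratio)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1A550]))
    folds = _kfold_indices(n, n_folds, rng)
    mse = np.zeros(len(lams))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        Dt, yt = Ds[mask], yc[mask]
        Gt = Dt.T @ Dt / Dt.shape[0]
        ct = Dt.T @ yt / Dt.shape[0]
        b = np.zeros(Ds.shape[1])
        for i, lam in enumerate(lams):
            cd_penalized_gram(Gt, ct, lam, -1.0, penalty_factor, b,
                              max_iter=200, tol=1e-5)
            r = yc[fold] - Ds[fold] @ b
            mse[i] += r @ r
    return lams, float(lams[int(np.argmin(mse))])


def _scaled_lasso_sigma(G, c, yty_n, penalty_factor, lam0, n):
    """Joint noise/coefficient estimation by the scaled Lasso.

    Alternates sigma^2 = RSS/n with a Lasso fit at lambda = sigma * lam0
    until the noise level stabilises; lam0 is the universal penalty
    sqrt(2 log P / n) on standardized columns.
    """
    sigma = math.sqrt(max(yty_n, 1e-12))
    b = np.zeros(G.shape[0])
    for _ in range(50):
        cd_penalized_gram(G, c, sigma * lam0, -1.0, penalty_factor, b,
                          max_iter=500, tol=1e-7)
        rss_n = max(yty_n - 2.0 * c @ b + b @ G @ b, 1e-12)
        new = math.sqrt(rss_n)
        if abs(new - sigma) < 1e-5 * sigma:
            sigma = new
            break
        sigma = new
    return sigma


def fit_debiased_lasso(
    Y,
    X,
    M_screened,
    C=None,
    weights=None,
    seed: int = 0,
    n_folds: int = 10,
    nodewise_lambda: str | float = "universal",
    noise_estimator: str = "scaled_lasso",
) -> DebiasedFit:
    """De-biased Lasso estimates, standard errors and p-values.

    The outcome model Y ~ X + M_screened + C is fit by Lasso (exposure and
    confounders unpenalized, initial lambda by ``n_folds``-fold
    cross-validation with deterministic fold assignment from ``seed``),
    then de-biased with a nodewise-regression approximation of the
    precision matrix.  ``nodewise_lambda`` is the shared nodewise penalty:
    'universal' uses sqrt(2 log P / n) on the standardized columns, 'cv'
    cross-validates a shared value, a float is used as given.  The noise
    level defaults to the scaled-Lasso estimate (joint iteration of
    sigma^2 = RSS/n with a Lasso at lambda = sigma sqrt(2 log P / n));
    ``noise_estimator='df'`` uses sigma^2 = RSS/(n - #nonzero) at the
    cross-validated fit instead.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    D, d, ncov = _assemble_design(X, M_screened, C)
    n, P = D.shape
    if d >= n:
        raise ValueError(f"screened dimension d={d} must be below n={n}")

    penalty_factor = np.zeros(P)
    penalty_factor[1 : 1 + d] = 1.0
    Ds, yc, mu, ybar, sd = _standardize(D, Y, weights)
    G = Ds.T @ Ds / n
    c = Ds.T @ yc / n

    _, lam0 = _cv_lasso_lambda(Ds, yc, penalty_factor, n_folds, seed)
    b_init = np.zeros(P)
    cd_penalized_gram(G, c, lam0, -1.0, penalty_factor, b_init)

    resid = yc - Ds @ b_init
    if noise_estimator == "scaled_lasso":
        yty_n = yc @ yc / n
        sigma2 = _scaled_lasso_sigma(
            G, c, yty_n, penalty_factor, np.sqrt(2.0 * np.log(P) / n), n
        ) ** 2
    elif noise_estimator == "df":
        s_hat = int((b_init != 0).sum())
        sigma2 = float(resid @ resid) / max(n - s_hat, 1)
    else:
        raise ValueError(f"unknown noise estimator {noise_estimator!r}")

    if nodewise_lambda == "universal":
        lam_node = np.sqrt(2.0 * np.log(P) / n)
    elif nodewise_lambda == "cv":
        # shared value cross-validated on a deterministic subset of nodes
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0DE]))
        probe = rng.choice(P, size=min(8, P), replace=False)
        vals = []
        for j in probe:
            keep = np.ones(P, dtype=bool)
            keep[j] = False
            pf = np.ones(P - 1)
            _, lj = _cv_lasso_lambda(Ds[:, keep], Ds[:, j], pf, 5, seed + int(j))
            vals.append(lj)
        lam_node = float(np.median(vals))
    else:
        lam_node = float(nodewise_lambda)

    # debias exposure + mediator coordinates
    targets = np.arange(1 + d)
    Theta = np.zeros((len(targets), P))
    for t, j in enumerate(targets):
        gamma = np.zeros(P)
        tau2 = cd_lasso_node(G, int(j), lam_node, gamma)
        row = -gamma / tau2
        row[j] = 1.0 / tau2
        Theta[t] = row

    b_deb = b_init[targets] + Theta @ (Ds.T @ resid) / n
    var_rows = np.einsum("tj,jk,tk->t", Theta, G, Theta)
    se = np.sqrt(sigma2 * var_rows / n)

    # back to the original scale
    b_orig = b_deb / sd[targets]
    se_orig = se / sd[targets]
    z = np.divide(b_orig, se_orig, out=np.zeros_like(b_orig), where=se_orig > 0)
    pvals = 2.0 * (1.0 - stats.norm.cdf(np.abs(z)))

    return DebiasedFit(
        beta_hat=b_orig[1:],
        sigma_hat=se_orig[1:],
        p_values=pvals[1:],
        gamma_hat=float(b_orig[0]),
        gamma_se=float(se_orig[0]),
        gamma_p=float(pvals[0]),
        lam_initial=lam0,
        sigma_noise=float(np.sqrt(sigma2)),
    )
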