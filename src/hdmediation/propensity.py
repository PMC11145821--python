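"""Propensity-score estimation and confounding-adjustment weights.

The propensity score pi_i = P(X_i = 1 | C_i) is estimated by
maximum-likelihood logistic regression of the exposure on the confounders
(with intercept).  Two weighting schemes convert the fitted scores into
per-sample balancing weights:

* inverse probability weighting (``ipw``): w_i = X_i/pi_i + (1-X_i)/(1-pi_i),
  unbounded as pi approaches 0 or 1;
* overlap weighting (``ow``): w_i = 1-pi_i for exposed, pi_i for unexposed,
  bounded in (0,1) and emphasising samples near pi = 0.5.  Under a
  logistic MLE score model, overlap weights exactly balance the weighted
  confounder means between the two exposure groups.

Regression adjustment (``ra``, confounders as covariates) and
propensity-score regression (``psr``, the fitted score as the single
covariate) are the two weight-free schemes; all four are routed through the
same weighted-least-squares engine.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from ._wls import WLSResult, wls_fit

logger = logging.getLogger(__name__)

__all__ = [
    "PropensityFit",
    "WeightVector",
    "fit_propensity",
    "compute_weights",
    "weighted_linear_fit",
    "weight_diagnostics",
    "ADJUSTMENTS",
]

#: the four supported confounding-adjustment schemes
ADJUSTMENTS = ("ra", "psr", "ipw", "ow")

#: symmetric clipping bound keeping scores strictly inside (0, 1)
PS_EPSILON = 1e-6


@dataclass
class PropensityFit:
    """Fitted propensity scores pi_i and the logistic coefficients."""

    scores: np.ndarray
    coefficients: np.ndarray
    converged: bool
    n_iterations: int


@dataclass
class WeightVector:
    """Per-sample balancing weights under one scheme ('ipw' or 'ow')."""

    scheme: str
    weights: np.ndarray
    source: PropensityFit | None = None


def fit_propensity(C: np.ndarray, X: np.ndarray) -> PropensityFit:
    """Maximum-likelihood logistic regression of X on C (with intercept).

    Perfect separation or non-convergence is reported through
    ``converged=False`` with scores clipped into (0, 1); an exposure vector
    with an empty class raises.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    X = np.asarray(X, dtype=float).ravel()
    if C.shape[0] != X.shape[0]:
        raise ValueError("C and X have different numbers of rows")
    if not np.isfinite(C).all():
        raise ValueError("C contains missing values")
    n1 = int(X.sum())
    if n1 == 0 or n1 == X.shape[0]:
        raise ValueError("one exposure class is empty; cannot fit a propensity model")

    # constant confounder columns carry no information and break the MLE;
    # they are dropped from the design and reported with coefficient 0
    informative = np.ptp(C, axis=0) > 0
    design = sm.add_constant(C[:, informative], has_constant="add")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            res = sm.Logit(X, design).fit(disp=False, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
            n_iter = int(res.mle_retvals.get("iterations", 0))
            params = res.params
        except Exception as exc:  # separation / convergence problems
            logger.warning("propensity fit flagged: %s", exc)
            converged = False
            # IRLS through GLM still returns finite (if extreme) estimates
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(X, design, family=sm.families.Binomial()).fit(
                    maxiter=50
                )
            n_iter = int(getattr(res, "fit_history", {}).get("iteration", 0))
            params = res.params
    scores = np.clip(res.predict(design), PS_EPSILON, 1.0 - PS_EPSILON)
    if not converged:
        logger.warning("propensity model did not converge; scores clipped")
    coefficients = np.zeros(C.shape[1] + 1)
    coefficients[0] = params[0]
    coefficients[1:][informative] = params[1:]
    return PropensityFit(
        scores=scores,
        coefficients=coefficients,
        converged=converged,
        n_iterations=n_iter,
    )


def compute_weights(fit: PropensityFit, X: np.ndarray, scheme: str) -> WeightVector:
    """Construct IPW or OW balancing weights from fitted scores."""
    if scheme not in ("ipw", "ow"):
        raise ValueError(f"unknown weighting scheme {scheme!r}; use 'ipw' or 'ow'")
    X = np.asarray(X, dtype=float).ravel()
    pi = np.clip(fit.scores, PS_EPSILON, 1.0 - PS_EPSILON)
    if pi.shape[0] != X.shape[0]:
        raise ValueError("scores and X are not aligned")
    if scheme == "ipw":
        w = X / pi + (1.0 - X) / (1.0 - pi)
    else:
        w = np.where(X == 1.0, 1.0 - pi, pi)
    return WeightVector(scheme=scheme, weights=w, source=fit)


def weighted_linear_fit(
    response: np.ndarray,
    design: np.ndarray,
    weights: np.ndarray | None = None,
    robust: bool = True,
    column_names=None,
) -> WLSResult:
    """Weighted least squares with sandwich (default) or naive errors.

    Thin public wrapper over the shared engine; with equal weights the point
    estimates reduce to ordinary least squares.
    """
    return wls_fit(design, response, weights=weights, robust=robust,
                   column_names=column_names)


def weight_diagnostics(weights: WeightVector) -> dict:
    """Max weight and effective sample size (sum w)^2 / sum w^2."""
    w = weights.weights
    ess = float(w.sum() ** 2 / (w**2).sum())
    out = {
        "scheme": weights.scheme,
        "max_weight": float(w.max()),
        "min_weight": float(w.min()),
        "effective_sample_size": ess,
    }
    logger.info(
        "weights[%s]: max=%.4g min=%.4g ESS=%.1f",
        weights.scheme, out["max_weight"], out["min_weight"], ess,
    )
    return out
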