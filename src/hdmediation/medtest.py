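"""Mediation-level inference: joint-significance tests over candidates.

A mediator is declared significant when both path effects are: the raw
statistic is P_raw = max(P_alpha, P_beta).  Two calibrations of that
statistic are provided:

* **JS-uniform** treats P_raw as uniform under the null and applies
  Benjamini–Hochberg; valid but conservative, because under the composite
  null P_max is stochastically smaller than uniform.
* **JS-mixture** decomposes the composite null into its three components
  (both effects null; alpha null only; beta null only), estimates the
  component proportions from the two marginal p-value sets with a
  Storey-type estimator, and plugs them into a pointwise FDR estimate:
  under H00, Pr(P_max <= t) = t^2; under H01/H10 it is approximated by t.

Per-candidate alpha inference runs the adjusted exposure->mediator model of
the chosen confounding-adjustment scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._wls import wls_fit
from .datasets import MediationDataset
from .propensity import PropensityFit, WeightVector
from .screening import marginal_alpha

__all__ = [
    "CandidateInference",
    "MediationReport",
    "alpha_inference",
    "beta_inference",
    "js_uniform",
    "estimate_null_proportions",
    "js_mixture_fdr",
]


@dataclass
class CandidateInference:
    """Path-specific estimates and p-values for the candidate mediators."""

    mediator_index: np.ndarray
    mediator_id: np.ndarray
    alpha_hat: np.ndarray
    alpha_se: np.ndarray
    p_alpha: np.ndarray
    beta_hat: np.ndarray
    beta_se: np.ndarray
    p_beta: np.ndarray

    @property
    def alpha_beta(self) -> np.ndarray:
        return self.alpha_hat * self.beta_hat


@dataclass
class MediationReport:
    """Final per-mediator mediation calls plus global effect summaries."""

    table: pd.DataFrame
    gamma_hat: float
    test_method: str
    adjustment: str
    level: float = 0.05
    extras: dict = field(default_factory=dict)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def alpha_inference(
    dataset: MediationDataset,
    candidate_set,
    adjustment: str = "ow",
    ps_fit: PropensityFit | None = None,
    weights: WeightVector | None = None,
    robust_weighted_se: bool = True,
):
    """Exposure->mediator inference for each candidate under ``adjustment``.

    RA fits M_k ~ (1, X, C) by OLS; PSR uses the fitted propensity score as
    the single covariate; IPW/OW fit the RA model by weighted least squares
    with sandwich standard errors.  Returns (alpha_hat, se, p) arrays
    aligned with ``candidate_set`` (empty arrays for an empty set).
    """
    idx = np.asarray(candidate_set, dtype=int)
    if idx.size == 0:
        z = np.empty(0)
        return z, z.copy(), z.copy()
    if np.ptp(dataset.X) == 0.0:
        raise ValueError("exposure is constant; no exposure contrast")
    return marginal_alpha(
        dataset, adjustment, ps_fit=ps_fit, weights=weights, columns=idx,
        robust_weighted_se=robust_weighted_se,
    )


def beta_inference(
    dataset: MediationDataset,
    candidate_set,
    adjustment: str = "ow",
    ps_fit: PropensityFit | None = None,
):
    """Mediator->outcome inference from the joint outcome regression.

    Fits Y ~ (1, X, M_candidates, covariates) by OLS where the covariates
    are the confounders (RA/IPW/OW) or the propensity score (PSR), and
    returns (beta_hat, se, p) for the mediator block.
    """
    idx = np.asarray(candidate_set, dtype=int)
    if idx.size == 0:
        z = np.empty(0)
        return z, z.copy(), z.copy(), np.nan
    n = dataset.n
    if adjustment == "psr":
        if ps_fit is None:
            raise ValueError("PSR beta inference requires the fitted propensity score")
        cov = ps_fit.scores[:, None]
    else:
        cov = dataset.C
    Z = np.column_stack([np.ones(n), dataset.X, dataset.M[:, idx], cov])
    res = wls_fit(Z, dataset.Y, robust=False)
    sl = slice(2, 2 + idx.size)
    return res.params[sl], res.bse[sl], res.pvalues[sl], float(res.params[1])


def _validate_pvalues(*vectors):
    for v in vectors:
        v = np.asarray(v, dtype=float)
        if v.size and (np.nanmin(v) < 0.0 or np.nanmax(v) > 1.0):
            raise ValueError("p-values must lie in [0, 1]")


def js_uniform(p_alpha, p_beta, level: float = 0.05, n_tests: int | None = None):
    """Joint-significance max-P test with Benjamini–Hochberg adjustment.

    Returns ``(p_raw, p_bh, significant)`` where
    p_raw_k = max(p_alpha_k, p_beta_k) and p_bh is the BH step-up adjusted
    value min(p_raw * q / rank, 1) with monotonicity enforcement.
    ``n_tests`` overrides the BH multiplier q (default: the number of
    candidates supplied); the classic two-stage workflow corrects against
    the full mediator universe rather than the post-selection candidate
    count, which is how it retains its very low false-discovery proportion.
    """
    p_alpha = np.asarray(p_alpha, dtype=float)
    p_beta = np.asarray(p_beta, dtype=float)
    if p_alpha.shape != p_beta.shape:
        raise ValueError("p-value vectors differ in length")
    _validate_pvalues(p_alpha, p_beta)
    p_raw = np.maximum(p_alpha, p_beta)
    q = p_raw.size
    if q == 0:
        return p_raw, p_raw.copy(), np.zeros(0, dtype=bool)
    multiplier = q if n_tests is None else int(n_tests)
    if multiplier < q:
        raise ValueError("n_tests cannot be smaller than the candidate count")
    order = np.argsort(p_raw, kind="stable")
    ranked = p_raw[order] * multiplier / np.arange(1, q + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    p_bh = np.empty(q)
    p_bh[order] = np.minimum(adj, 1.0)
    return p_raw, p_bh, p_bh <= level


def estimate_null_proportions(p_alpha, p_beta, storey_lambda: float = 0.5):
    """Estimate the 3-component mixture-null proportions.

    Marginal null fractions for the alpha and beta p-value sets come from
    the Storey estimator  pi0 = #{p > lambda} / ((1 - lambda) q)  (clipped
    to [0, 1]); cross-independence combines them into
    (pi00, pi01, pi10) = (pa*pb, pa*(1-pb), (1-pa)*pb), which sum to at
    most 1 by construction.
    """
    p_alpha = np.asarray(p_alpha, dtype=float)
    p_beta = np.asarray(p_beta, dtype=float)
    if p_alpha.size < 2 or p_beta.size < 2:
        raise ValueError("need at least 2 candidates to estimate null proportions")
    _validate_pvalues(p_alpha, p_beta)
    q = p_alpha.size

    def storey(p):
        return min(1.0, (p > storey_lambda).sum() / ((1.0 - storey_lambda) * q))

    pa0, pb0 = storey(p_alpha), storey(p_beta)
    return pa0 * pb0, pa0 * (1.0 - pb0), (1.0 - pa0) * pb0


def js_mixture_fdr(p_alpha, p_beta, proportions=None, level: float = 0.05):
    """Pointwise FDR of the max-P statistic under the 3-component null.

    At threshold t the expected false positives are
    V00 = q pi00 t^2,  V01 = q pi01 t,  V10 = q pi10 t, and
    FDR(t) = (V00 + V01 + V10) / max(R(t), 1) with R(t) the count of
    P_raw <= t, clipped to [0, 1].  Each candidate is evaluated at its own
    P_raw; a step-up monotonicity correction (cumulative minimum from the
    largest threshold) makes the calls threshold-consistent.  Returns
    ``(p_raw, fdr, significant)``.
    """
    p_alpha = np.asarray(p_alpha, dtype=float)
    p_beta = np.asarray(p_beta, dtype=float)
    if p_alpha.shape != p_beta.shape:
        raise ValueError("p-value vectors differ in length")
    _validate_pvalues(p_alpha, p_beta)
    q = p_alpha.size
    p_raw = np.maximum(p_alpha, p_beta)
    if q == 0:
        return p_raw, p_raw.copy(), np.zeros(0, dtype=bool)
    if proportions is None:
        proportions = estimate_null_proportions(p_alpha, p_beta)
    pi00, pi01, pi10 = proportions
    if min(pi00, pi01, pi10) < 0 or pi00 + pi01 + pi10 > 1.0 + 1e-12:
        raise ValueError(f"invalid null proportions {proportions}")

    t = p_raw
    if np.any((t < 0) | (t > 1)):
        raise ValueError("thresholds must lie in [0, 1]")
    order = np.argsort(t, kind="stable")
    ts = t[order]
    R = np.searchsorted(ts, ts, side="right")      # count of p_raw <= t
    V = q * (pi00 * ts**2 + pi01 * ts + pi10 * ts)
    fdr_sorted = np.clip(V / np.maximum(R, 1), 0.0, 1.0)
    fdr_sorted = np.minimum.accumulate(fdr_sorted[::-1])[::-1]
    fdr = np.empty(q)
    fdr[order] = fdr_sorted
    return p_raw, fdr, fdr <= level


def build_report(
    inference: CandidateInference,
    p_adjusted: np.ndarray,
    significant: np.ndarray,
    p_raw: np.ndarray,
    gamma_hat: float,
    test_method: str,
    adjustment: str,
    level: float = 0.05,
    percent_te_absolute: bool = False,
) -> MediationReport:
    """Assemble the final per-mediator table with %TE for significant calls.

    %TE_k = 100 * ab_k / (gamma_hat + sum of significant ab_j); with
    ``percent_te_absolute`` the absolute values are used in both places.
    """
    ab = inference.alpha_beta
    sig_ab = ab[significant]
    if percent_te_absolute:
        denom = abs(gamma_hat) + np.abs(sig_ab).sum()
        num = np.abs(ab)
    else:
        denom = gamma_hat + sig_ab.sum()
        num = ab
    pct = 100.0 * num / denom if denom != 0 else np.full_like(ab, np.nan)
    table = pd.DataFrame(
        {
            "mediator_index": inference.mediator_index,
            "mediator_id": inference.mediator_id,
            "alpha_hat": inference.alpha_hat,
            "alpha_se": inference.alpha_se,
            "p_alpha": inference.p_alpha,
            "beta_hat": inference.beta_hat,
            "beta_se": inference.beta_se,
            "p_beta": inference.p_beta,
            "alpha_beta": ab,
            "percent_TE": pct,
            "p_raw": p_raw,
            "p_adjusted": p_adjusted,
            "significant": significant,
        }
    )
    return MediationReport(
        table=table,
        gamma_hat=gamma_hat,
        test_method=test_method,
        adjustment=adjustment,
        level=level,
    )
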