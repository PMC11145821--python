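"""End-to-end workflows and the simulation benchmark.

Two workflows are orchestrated over any confounding-adjustment scheme
(ra / psr / ipw / ow):

* ``hima``   — SIS screen -> MCP selection -> per-candidate alpha/beta
  inference -> JS-uniform max-P test with BH adjustment;
* ``mhima2`` — SIS screen -> de-biased Lasso inference over all screened
  candidates -> JS-mixture composite-null FDR.

The benchmark replays either workflow over replicated synthetic datasets
and summarises detection (per-mediator TPR, overall TPR, FDP) and
estimation (Monte-Carlo mean and MSE of the indirect-effect product) for
the true mediators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MediationDataset
from .medtest import (
    CandidateInference,
    MediationReport,
    alpha_inference,
    beta_inference,
    build_report,
    estimate_null_proportions,
    js_mixture_fdr,
    js_uniform,
)
from .penalized import fit_debiased_lasso, fit_mcp
from .propensity import ADJUSTMENTS, compute_weights, fit_propensity, weight_diagnostics
from .screening import screen_mediators, sis_dimension
from .simdata import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "WorkflowConfig",
    "SimulationMetrics",
    "run_workflow",
    "evaluate_replications",
    "run_benchmark",
]


@dataclass
class WorkflowConfig:
    """Configuration of one analysis run."""

    test_method: str = "mhima2"       # 'hima' or 'mhima2'
    adjustment: str = "ow"            # 'ra', 'psr', 'ipw', 'ow'
    level: float = 0.05
    d: int | None = None              # override of the SIS dimension
    screening_basis: str = "beta"
    seed: int = 0
    percent_te_absolute: bool = False

    def __post_init__(self) -> None:
        if self.test_method not in ("hima", "mhima2"):
            raise ValueError(f"unknown test method {self.test_method!r}")
        if self.adjustment not in ADJUSTMENTS:
            raise ValueError(f"unknown adjustment {self.adjustment!r}")


@dataclass
class SimulationMetrics:
    """Detection and estimation metrics over benchmark replications."""

    true_indices: np.ndarray
    true_alpha_beta: np.ndarray
    tpr_per_true_mediator: np.ndarray
    overall_tpr: float
    fdp: float
    mean_est: np.ndarray              # conditional on a significant call
    mse: np.ndarray
    mean_est_all: np.ndarray          # over all replications with an estimate
    mse_all: np.ndarray
    n_selected_per_true: np.ndarray
    reps: int

    def mc_se(self, rate: float) -> float:
        """Monte-Carlo standard error of a rate metric."""
        return float(np.sqrt(rate * (1.0 - rate) / self.reps))


def _empty_inference() -> CandidateInference:
    z = np.empty(0)
    return CandidateInference(
        mediator_index=np.empty(0, dtype=int),
        mediator_id=np.empty(0, dtype=object),
        alpha_hat=z, alpha_se=z.copy(), p_alpha=z.copy(),
        beta_hat=z.copy(), beta_se=z.copy(), p_beta=z.copy(),
    )


def run_workflow(dataset: MediationDataset, config: WorkflowConfig) -> MediationReport:
    """Run one complete mediation analysis and return the report.

    Deterministic given ``config.seed`` (which drives the cross-validation
    folds of the de-biased Lasso).
    """
    dataset.require_both_groups()
    adj = config.adjustment

    ps_fit = None
    weights = None
    if adj != "ra":
        ps_fit = fit_propensity(dataset.C, dataset.X)
    if adj in ("ipw", "ow"):
        weights = compute_weights(ps_fit, dataset.X, adj)
        weight_diagnostics(weights)

    screen = screen_mediators(
        dataset, adjustment=adj, basis=config.screening_basis,
        d=config.d, ps_fit=ps_fit, weights=weights,
    )
    logger.info("screening kept d=%d of p=%d mediators", screen.d, dataset.p)
    kept = screen.kept
    M_kept = dataset.M[:, kept]
    covariates = ps_fit.scores[:, None] if adj == "psr" else dataset.C

    extras = {"screen": screen, "ps_fit": ps_fit, "weights": weights}

    if config.test_method == "hima":
        mcp = fit_mcp(dataset.Y, dataset.X, M_kept, covariates)
        cand = kept[mcp.selected]
        extras["mcp"] = mcp
        logger.info("MCP selected %d of %d screened mediators", cand.size, screen.d)
        if cand.size == 0:
            logger.info("empty candidate set after MCP; returning empty report")
            report = build_report(
                _empty_inference(), np.empty(0), np.zeros(0, dtype=bool),
                np.empty(0), mcp.gamma_hat, "hima", adj, config.level,
            )
            report.extras = extras
            return report
        a_hat, a_se, p_a = alpha_inference(dataset, cand, adj, ps_fit, weights)
        b_hat, b_se, p_b, gamma_hat = beta_inference(dataset, cand, adj, ps_fit)
        p_raw, p_adj, sig = js_uniform(p_a, p_b, config.level, n_tests=dataset.p)
    else:
        deb = fit_debiased_lasso(
            dataset.Y, dataset.X, M_kept, covariates, seed=config.seed,
        )
        extras["debiased"] = deb
        cand = kept
        a_hat, a_se, p_a = alpha_inference(dataset, cand, adj, ps_fit, weights)
        b_hat, b_se, p_b = deb.beta_hat, deb.sigma_hat, deb.p_values
        gamma_hat = deb.gamma_hat
        proportions = estimate_null_proportions(p_a, p_b)
        extras["null_proportions"] = proportions
        p_raw, p_adj, sig = js_mixture_fdr(p_a, p_b, proportions, config.level)

    inference = CandidateInference(
        mediator_index=cand,
        mediator_id=np.asarray(dataset.mediator_ids)[cand],
        alpha_hat=a_hat, alpha_se=a_se, p_alpha=p_a,
        beta_hat=b_hat, beta_se=b_se, p_beta=p_b,
    )
    report = build_report(
        inference, p_adj, sig, p_raw, gamma_hat,
        config.test_method, adj, config.level, config.percent_te_absolute,
    )
    report.extras = extras
    return report


def evaluate_replications(reports, truth) -> SimulationMetrics:
    """Summarise replicated reports against the generating truth.

    ``truth`` is ``(true_indices, true_alpha_beta)`` with 0-based mediator
    indices, or a :class:`~hdmediation.simdata.SimulationConfig`.
    TPR_k is the fraction of replications in which true mediator k is
    significant; FDP is the mean over replications of
    (#false positives / max(#significant, 1)).  Mean/MSE of the product
    estimate are reported both conditional on a significant call (primary)
    and over every replication in which the mediator reaches the candidate
    stage.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no replications supplied")
    if isinstance(truth, SimulationConfig):
        true_idx = truth.true_mediators
        true_ab = truth.alpha_beta[true_idx]
    else:
        true_idx, true_ab = truth
        true_idx = np.asarray(true_idx, dtype=int)
        true_ab = np.asarray(true_ab, dtype=float)
    true_set = set(true_idx.tolist())

    reps = len(reports)
    hits = np.zeros((reps, true_idx.size), dtype=bool)
    est_sig = [[] for _ in true_idx]
    est_all = [[] for _ in true_idx]
    fdp = np.zeros(reps)
    for r, rep in enumerate(reports):
        tab = rep.table
        sig_idx = set(tab.loc[tab["significant"], "mediator_index"].tolist())
        n_sig = len(sig_idx)
        n_false = len(sig_idx - true_set)
        fdp[r] = n_false / max(n_sig, 1)
        by_index = dict(zip(tab["mediator_index"], tab["alpha_beta"]))
        for t, k in enumerate(true_idx):
            if int(k) in by_index:
                est_all[t].append(by_index[int(k)])
                if int(k) in sig_idx:
                    hits[r, t] = True
                    est_sig[t].append(by_index[int(k)])

    tpr = hits.mean(axis=0)

    def _mean_mse(lists):
        means = np.full(true_idx.size, np.nan)
        mses = np.full(true_idx.size, np.nan)
        for t, vals in enumerate(lists):
            if vals:
                v = np.asarray(vals)
                means[t] = v.mean()
                mses[t] = np.mean((v - true_ab[t]) ** 2)
        return means, mses

    mean_sig, mse_sig = _mean_mse(est_sig)
    mean_all, mse_all = _mean_mse(est_all)
    return SimulationMetrics(
        true_indices=true_idx,
        true_alpha_beta=true_ab,
        tpr_per_true_mediator=tpr,
        overall_tpr=float(tpr.mean()),
        fdp=float(fdp.mean()),
        mean_est=mean_sig,
        mse=mse_sig,
        mean_est_all=mean_all,
        mse_all=mse_all,
        n_selected_per_true=np.array([len(v) for v in est_sig]),
        reps=reps,
    )


def _rep_seeds(master_seed: int, n: int, p: int, rho: float, rep: int):
    """Counter-based per-replication seeds, independent of execution order."""
    ss = np.random.SeedSequence(
        [int(master_seed), int(n), int(p), int(round(rho * 1000)), int(rep)]
    )
    a, b = ss.generate_state(2)
    return int(a >> 1), int(b >> 1)


def _run_replication(scenario: SimulationConfig, configs, master_seed: int, rep: int):
    data_seed, wf_seed = _rep_seeds(master_seed, scenario.n, scenario.p, scenario.rho, rep)
    dataset = simulate_dataset(scenario, seed=data_seed)
    out = {}
    for key, cfg in configs.items():
        cfg_r = WorkflowConfig(
            test_method=cfg.test_method, adjustment=cfg.adjustment,
            level=cfg.level, d=cfg.d, screening_basis=cfg.screening_basis,
            seed=wf_seed, percent_te_absolute=cfg.percent_te_absolute,
        )
        out[key] = run_workflow(dataset, cfg_r)
    return out


def run_benchmark(
    scenario: SimulationConfig,
    methods=(("mhima2", "ow"),),
    reps: int = 500,
    seed: int = 0,
    workers: int = 1,
) -> dict:
    """Replicated benchmark of one scenario cell for each (method, adjustment).

    Returns ``{(method, adjustment): SimulationMetrics}``; all methods see
    the same replicated datasets.  Per-replication seeds are derived by a
    counter-based split of ``seed``, so parallel (``workers > 1``) and
    serial execution give identical results and any cell can be reproduced
    in isolation.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    d = sis_dimension(scenario.n)
    if min(d, scenario.p) >= scenario.n:
        raise ValueError(
            f"infeasible cell: screened dimension {min(d, scenario.p)} >= n={scenario.n}"
        )
    configs = {
        (m, a): WorkflowConfig(test_method=m, adjustment=a) for m, a in methods
    }
    if workers > 1:
        from joblib import Parallel, delayed

        all_reports = Parallel(n_jobs=workers)(
            delayed(_run_replication)(scenario, configs, seed, r) for r in range(reps)
        )
    else:
        all_reports = [
            _run_replication(scenario, configs, seed, r) for r in range(reps)
        ]
    metrics = {}
    for key in configs:
        metrics[key] = evaluate_replications(
            [rep[key] for rep in all_reports], scenario
        )
    return metrics


def metrics_frame(metrics: dict, scenario: SimulationConfig) -> pd.DataFrame:
    """Flatten benchmark metrics into a tidy table (one row per cell)."""
    rows = []
    for (method, adjustment), m in metrics.items():
        row = {
            "n": scenario.n, "p": scenario.p, "rho": scenario.rho,
            "test_method": method, "adjustment": adjustment, "reps": m.reps,
            "overall_tpr": m.overall_tpr, "fdp": m.fdp,
        }
        for t, k in enumerate(m.true_indices):
            label = f"M{k + 1}"
            row[f"tpr_{label}"] = m.tpr_per_true_mediator[t]
            row[f"mean_{label}"] = m.mean_est[t]
            row[f"mse_{label}"] = m.mse[t]
            row[f"mean_all_{label}"] = m.mean_est_all[t]
            row[f"mse_all_{label}"] = m.mse_all[t]
        row["tpr_mc_se"] = m.mc_se(m.overall_tpr)
        rows.append(row)
    return pd.DataFrame(rows)
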