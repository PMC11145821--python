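"""Synthetic data generator for the benchmark study conditions.

Emulates an observational epigenetic study: eight baseline confounders
(four correlated Gaussians, four Bernoulli), a binary exposure following a
logistic model in the confounders, ``p`` mediators (methylation-like
continuous variables) with a sparse exposure effect, and a continuous
outcome with a sparse mediator effect.  The first four mediators carry true
indirect effects alpha*beta = (0.16, 0.20, 0.25, 0.30); mediators 5-6 have
alpha != 0 but beta = 0, mediators 7-8 the reverse, and the rest are null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import MediationDataset

__all__ = [
    "SimulationConfig",
    "generate_confounders",
    "generate_exposure",
    "generate_mediators",
    "generate_outcome",
    "simulate_dataset",
]

_DEFAULT_CONF_EFFECT = (0.2, 0.2, 0.3, 0.3, 0.2, 0.2, 0.3, 0.3)

#: leading non-zero entries of the exposure->mediator effect vector
_ALPHA_HEAD = (0.4, 0.4, 0.5, 0.5, 0.5, 0.5)
#: leading entries of the mediator->outcome effect vector
_BETA_HEAD = (0.4, 0.5, 0.5, 0.6, 0.0, 0.0, 0.5, 0.5)


def _padded(head: tuple[float, ...], p: int) -> np.ndarray:
    out = np.zeros(p)
    out[: min(len(head), p)] = head[: min(len(head), p)]
    return out


@dataclass
class SimulationConfig:
    """Parameters of one simulation scenario.

    Defaults reproduce the benchmark's baseline scenario.  ``rho`` is the
    AR(1) correlation parameter of the mediator error terms: for
    ``rho == 0`` errors are i.i.d. with standard deviation
    ``mediator_error_sd`` (default sqrt(1.2), i.e. variance 1.2); for
    ``rho > 0`` errors are drawn from a p-variate normal with covariance
    rho^|k-k'| and unit diagonal (set ``correlated_errors_scaled=True`` to
    scale that covariance by the error variance instead).
    """

    n: int = 500
    p: int = 1000
    rho: float = 0.0
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    theta: np.ndarray = field(
        default_factory=lambda: np.array(_DEFAULT_CONF_EFFECT)
    )
    phi: np.ndarray = field(
        default_factory=lambda: np.array(_DEFAULT_CONF_EFFECT)
    )
    eta: np.ndarray = field(
        default_factory=lambda: np.array(_DEFAULT_CONF_EFFECT)
    )
    gamma: float = 0.5
    intercept_a: float = 0.5
    mediator_error_sd: float = math.sqrt(1.2)
    correlated_errors_scaled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.p < 1:
            raise ValueError(f"p must be >= 1, got {self.p}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.alpha is None:
            self.alpha = _padded(_ALPHA_HEAD, self.p)
        else:
            self.alpha = np.asarray(self.alpha, dtype=float)
        if self.beta is None:
            self.beta = _padded(_BETA_HEAD, self.p)
        else:
            self.beta = np.asarray(self.beta, dtype=float)
        for name in ("theta", "phi", "eta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.alpha.shape != (self.p,) or self.beta.shape != (self.p,):
            raise ValueError("alpha and beta must have length p")

    @property
    def alpha_beta(self) -> np.ndarray:
        """Elementwise true indirect effects alpha_k * beta_k."""
        return self.alpha * self.beta

    @property
    def true_mediators(self) -> np.ndarray:
        """Indices with non-zero indirect effect (0-based)."""
        return np.flatnonzero(self.alpha_beta != 0.0)


def _streams(seed: int, n_children: int = 4) -> list[np.random.Generator]:
    # independent streams per component so changing p leaves X untouched
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n_children)]


def generate_confounders(n: int, seed: int = 0) -> np.ndarray:
    """Draw the n x 8 confounder matrix.

    Columns 0-3 are 4-variate normal, zero mean, unit variances and 0.3
    pairwise covariances; columns 4-7 are independent Bernoulli(0.3).
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cov = np.full((4, 4), 0.3)
    np.fill_diagonal(cov, 1.0)
    cont = rng.multivariate_normal(np.zeros(4), cov, size=n, method="cholesky")
    binary = (rng.random((n, 4)) < 0.3).astype(float)
    return np.hstack([cont, binary])


def generate_exposure(
    C: np.ndarray, theta: np.ndarray | None = None, seed: int = 0
) -> np.ndarray:
    """Draw the binary exposure X_i ~ Bernoulli(expit(theta' C_i)).

    The exposure model has no intercept: at C = 0 the exposure probability
    is exactly 0.5.
    """
    C = np.asarray(C, dtype=float)
    theta = (
        np.array(_DEFAULT_CONF_EFFECT)
        if theta is None
        else np.asarray(theta, dtype=float)
    )
    if C.ndim != 2 or C.shape[1] != theta.shape[0]:
        raise ValueError(
            f"C has {C.shape[1] if C.ndim == 2 else '?'} columns but theta "
            f"has length {theta.shape[0]}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    prob = 1.0 / (1.0 + np.exp(-(C @ theta)))
    return (rng.random(C.shape[0]) < prob).astype(float)


def _ar1_errors(
    rng: np.random.Generator, n: int, p: int, rho: float, sd: float
) -> np.ndarray:
    """Errors with covariance sd^2 * rho^|k-k'| via the AR(1) recursion."""
    z = rng.standard_normal((n, p))
    if rho == 0.0:
        return sd * z
    e = np.empty((n, p))
    e[:, 0] = z[:, 0]
    scale = math.sqrt(1.0 - rho * rho)
    for k in range(1, p):
        e[:, k] = rho * e[:, k - 1] + scale * z[:, k]
    return sd * e


def generate_mediators(
    X: np.ndarray,
    C: np.ndarray,
    config: SimulationConfig,
    seed: int = 0,
) -> np.ndarray:
    """Draw the n x p mediator matrix M_ki = a_k + alpha_k X_i + phi'C_i + e_ki.

    The per-mediator intercepts a_k ~ U(0,1) are drawn once per mediator and
    shared across individuals.  With rho = 0 the errors are i.i.d.
    N(0, mediator_error_sd^2); with rho > 0 they follow the AR(1) covariance
    rho^|k-k'| (unit diagonal unless ``correlated_errors_scaled``).
    """
    if not 0.0 <= config.rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {config.rho}")
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    if X.shape[0] != C.shape[0]:
        raise ValueError("X and C have different numbers of rows")
    rng_a, rng_e = _streams(seed, 2)
    a = rng_a.random(config.p)
    if config.rho == 0.0:
        sd = config.mediator_error_sd
    else:
        sd = config.mediator_error_sd if config.correlated_errors_scaled else 1.0
    e = _ar1_errors(rng_e, X.shape[0], config.p, config.rho, sd)
    shared = C @ config.phi
    return a[None, :] + np.outer(X, config.alpha) + shared[:, None] + e


def generate_outcome(
    X: np.ndarray,
    M: np.ndarray,
    C: np.ndarray,
    config: SimulationConfig,
    seed: int = 0,
) -> np.ndarray:
    """Draw Y_i = a + gamma X_i + beta' M_i + eta' C_i + eps_i, eps ~ N(0,1)."""
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    C = np.asarray(C, dtype=float)
    if not (X.shape[0] == M.shape[0] == C.shape[0]):
        raise ValueError("X, M and C have different numbers of rows")
    if M.shape[1] != config.beta.shape[0]:
        raise ValueError("M column count does not match beta length")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    eps = rng.standard_normal(X.shape[0])
    return (
        config.intercept_a
        + config.gamma * X
        + M @ config.beta
        + C @ config.eta
        + eps
    )


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> MediationDataset:
    """Generate one full (C, X, M, Y) replication under ``config``.

    One master seed deterministically reproduces the whole dataset; the
    component generators draw from independent child streams.
    """
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    s_conf, s_expo, s_med, s_out = [int(c.generate_state(1)[0] >> 1) for c in ss.spawn(4)]
    C = generate_confounders(config.n, seed=s_conf)
    X = generate_exposure(C, config.theta, seed=s_expo)
    M = generate_mediators(X, C, config, seed=s_med)
    Y = generate_outcome(X, M, C, config, seed=s_out)
    return MediationDataset(
        X=X,
        Y=Y,
        M=M,
        C=C,
        sample_ids=np.array([f"s{i}" for i in range(config.n)]),
        mediator_ids=np.array([f"M{k + 1}" for k in range(config.p)]),
        truth_alpha=config.alpha.copy(),
        truth_beta=config.beta.copy(),
    )
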