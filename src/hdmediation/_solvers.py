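"""Numba coordinate-descent kernels for penalized least squares.

All kernels work on the Gram formulation of the problem: for a design with
standardized columns (unit population variance, so diag(G) = 1 on penalized
coordinates), minimise

    (1/2) b' G b - c' b + sum_j pen(b_j)

where G = X'X/n and c = X'y/n.  ``pen`` is the minimax concave penalty
(MCP) with concavity ``delta`` (delta = inf recovers the Lasso), applied
only where ``penalty_factor`` is non-zero.  Coordinate updates use the
closed-form firm-thresholding rule; with G_jj = 1 each update is exact, so
the objective is non-increasing across sweeps.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["cd_penalized_gram", "cd_lasso_node", "mcp_penalty_value"]


@njit(cache=True)
def _soft(z: float, lam: float) -> float:
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


@njit(cache=True)
def _mcp_update(z: float, gjj: float, lam: float, delta: float) -> float:
    # firm-thresholding solution of (1/2)g b^2 - z b + MCP(b); exact for g=1
    if abs(z) <= delta * lam * gjj:
        denom = gjj - 1.0 / delta
        if denom <= 0.0:
            return z / gjj if abs(z) > delta * lam * gjj else 0.0
        return _soft(z, lam) / denom
    return z / gjj


@njit(cache=True)
def cd_penalized_gram(
    G: np.ndarray,
    c: np.ndarray,
    lam: float,
    delta: float,
    penalty_factor: np.ndarray,
    beta: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> int:
    """In-place coordinate descent; returns the number of sweeps used.

    ``delta <= 0`` is interpreted as delta = inf (Lasso).  ``beta`` is the
    warm start and is overwritten with the solution.
    """
    P = G.shape[0]
    r = c - G @ beta  # gradient residual: c - G b
    active = np.zeros(P, dtype=np.bool_)
    sweeps = 0
    while sweeps < max_iter:
        # full sweep over all coordinates
        max_delta = 0.0
        for j in range(P):
            bj = beta[j]
            z = r[j] + G[j, j] * bj
            if penalty_factor[j] == 0.0:
                new = z / G[j, j]
            elif delta <= 0.0:
                new = _soft(z, lam * penalty_factor[j]) / G[j, j]
            else:
                new = _mcp_update(z, G[j, j], lam * penalty_factor[j], delta)
            diff = new - bj
            if diff != 0.0:
                beta[j] = new
                for l in range(P):
                    r[l] -= G[l, j] * diff
                if abs(diff) > max_delta:
                    max_delta = abs(diff)
            active[j] = new != 0.0 or penalty_factor[j] == 0.0
        sweeps += 1
        if max_delta < tol:
            return sweeps
        # inner iterations restricted to the active set
        while sweeps < max_iter:
            max_delta = 0.0
            for j in range(P):
                if not active[j]:
                    continue
                bj = beta[j]
                z = r[j] + G[j, j] * bj
                if penalty_factor[j] == 0.0:
                    new = z / G[j, j]
                elif delta <= 0.0:
                    new = _soft(z, lam * penalty_factor[j]) / G[j, j]
                else:
                    new = _mcp_update(z, G[j, j], lam * penalty_factor[j], delta)
                diff = new - bj
                if diff != 0.0:
                    beta[j] = new
                    for l in range(P):
                        r[l] -= G[l, j] * diff
                    if abs(diff) > max_delta:
                        max_delta = abs(diff)
            sweeps += 1
            if max_delta < tol:
                break
    return sweeps


@njit(cache=True)
def cd_lasso_node(
    G: np.ndarray,
    j: int,
    lam: float,
    gamma: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> float:
    """Nodewise Lasso of column j on the remaining columns, via the Gram.

    Minimises (1/2n)||X_j - X_{-j} g||^2 + lam ||g||_1.  ``gamma`` has
    length P with entry j ignored (kept at 0).  Returns
    tau_j^2 = G_jj - G_{j,-j} g + lam ||g||_1, the debiasing normaliser.
    """
    P = G.shape[0]
    # r_l = G_lj - sum_m G_lm gamma_m  (for l != j)
    r = G[:, j].copy()
    for m in range(P):
        if m != j and gamma[m] != 0.0:
            for l in range(P):
                r[l] -= G[l, m] * gamma[m]
    for it in range(max_iter):
        max_delta = 0.0
        for l in range(P):
            if l == j:
                continue
            gl = gamma[l]
            z = r[l] + G[l, l] * gl
            new = _soft(z, lam) / G[l, l]
            diff = new - gl
            if diff != 0.0:
                gamma[l] = new
                for m in range(P):
                    r[m] -= G[m, l] * diff
                if abs(diff) > max_delta:
                    max_delta = abs(diff)
        if max_delta < tol:
            break
    tau2 = G[j, j]
    l1 = 0.0
    for l in range(P):
        if l != j:
            tau2 -= G[j, l] * gamma[l]
            l1 += abs(gamma[l])
    return tau2 + lam * l1


def mcp_penalty_value(beta: float, lam: float, delta: float) -> float:
    """MCP penalty: lam(|b| - b^2/(2 lam delta)) below the plateau
    |b| = delta*lam, and lam^2 delta / 2 beyond it."""
    ab = abs(beta)
    if ab < delta * lam:
        return lam * (ab - ab * ab / (2.0 * lam * delta))
    return 0.5 * lam * lam * delta
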