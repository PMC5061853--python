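"""Closed-form transit-time and mean-age theory for autonomous systems.

For a constant compartmental system dx/dt = B x + s with exponentially
stable B, the classical reservoir-theory quantities are available in
closed form at the equilibrium x* = -B^{-1} s:

* per-pool remaining transit times  r^T = -(1,...,1) B^{-1},
* transfer probabilities            p_ij = -b_ji / b_ii,
* system transit time               R = r^T beta,   beta = s / sum(s),
* turnover time                     U = sum(x*) / sum(s)  (= R),
* equilibrium mean ages             abar* = -(X*)^{-1} B^{-1} X* 1,
* system mean age                   M = r^T eta,    eta = x* / sum(x*).

All linear algebra goes through solves rather than explicit inverses,
which matters for stiff rate matrices whose timescales span several
orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


__all__ = [
    "AutonomousSummary",
    "equilibrium",
    "pool_transit_times",
    "transfer_probabilities",
    "transit_time",
    "turnover_time",
    "equilibrium_mean_ages",
    "summarize",
]

_COND_WARN = 1e12


def _check_B(B: np.ndarray) -> np.ndarray:
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("B must be square")
    sv = np.linalg.svd(B, compute_uv=False)
    if sv[-1] <= sv[0] * np.finfo(float).eps * B.shape[0]:
        raise np.linalg.LinAlgError(
            f"B is singular to working precision (smallest singular value {sv[-1]:.3e})")
    if sv[0] / sv[-1] > _COND_WARN:
        import warnings
        warnings.warn(f"B is ill-conditioned (cond ~ {sv[0] / sv[-1]:.2e})", stacklevel=3)
    return B


def equilibrium(B, s) -> np.ndarray:
    """Equilibrium mass x* = -B^{-1} s, computed by a linear solve."""
    B = _check_B(B)
    s = np.asarray(s, dtype=float)
    return np.linalg.solve(B, -s)


def pool_transit_times(B) -> np.ndarray:
    """Mean remaining transit time r_i for a particle entering pool i.

    Satisfies 0 = B^T r + 1, i.e. r^T = -(1,...,1) B^{-1}; equivalently
    the renewal relation r_i = -1/b_ii + sum_{j != i} p_ij r_j.
    """
    B = _check_B(B)
    ones = np.ones(B.shape[0])
    return np.linalg.solve(B.T, -ones)


def transfer_probabilities(B) -> np.ndarray:
    """Jump-chain matrix p_ij = -b_ji / b_ii (probability pool i -> j).

    Row i sums to at most 1; the deficit 1 - sum_j p_ij is the
    probability of leaving the system directly from pool i.
    """
    B = np.asarray(B, dtype=float)
    diag = np.diag(B)
    if np.any(diag == 0):
        raise ValueError("zero diagonal entry: transfer probabilities undefined")
    P = -(B.T / diag[:, None])
    np.fill_diagonal(P, 0.0)
    return P


def transit_time(B, s) -> float:
    """System transit time R = -(1,...,1) B^{-1} beta (mean age at exit)."""
    s = np.asarray(s, dtype=float)
    total = s.sum()
    if total <= 0:
        raise ValueError("transit time requires a nonzero total input flux")
    return float(pool_transit_times(B) @ (s / total))


def turnover_time(B, s) -> float:
    """Turnover time U = sum(x*) / sum(s); equals R at equilibrium."""
    s = np.asarray(s, dtype=float)
    total = s.sum()
    if total <= 0:
        raise ValueError("turnover time requires a nonzero total input flux")
    return float(equilibrium(B, s).sum() / total)


def equilibrium_mean_ages(B, s) -> tuple[np.ndarray, float]:
    """Equilibrium mean-age vector abar* and system mean age M.

    abar* = -(X*)^{-1} B^{-1} X* (1,...,1)^T with X* = diag(x*), and
    M = -(1,...,1) B^{-1} eta is the eta-weighted mean of abar*.
    Refuses systems whose equilibrium has a nonpositive pool (the
    mean-age equation divides by the pool masses).
    """
    B = _check_B(B)
    x_star = equilibrium(B, s)
    bad = np.flatnonzero(x_star <= 0)
    if bad.size:
        raise ValueError(
            f"equilibrium mass of pool(s) {[int(i) + 1 for i in bad]} is nonpositive; "
            "mean ages are undefined there")
    abar = -np.linalg.solve(B, x_star) / x_star
    eta = x_star / x_star.sum()
    return abar, float(abar @ eta)


@dataclass
class AutonomousSummary:
    """All equilibrium quantities of an autonomous compartmental system."""

    x_star: np.ndarray   # equilibrium mass
    r: np.ndarray        # per-pool remaining transit times
    p: np.ndarray        # transfer probabilities, zero diagonal
    beta: np.ndarray     # input fractions
    eta: np.ndarray      # equilibrium mass fractions
    R: float             # system transit time
    M: float             # system mean age
    U: float             # turnover time (= R)
    a_star: np.ndarray   # equilibrium mean ages

    def to_dict(self) -> dict:
        return {
            "x_star": self.x_star.tolist(),
            "r": self.r.tolist(),
            "p": self.p.tolist(),
            "beta": self.beta.tolist(),
            "eta": self.eta.tolist(),
            "R": self.R,
            "M": self.M,
            "U": self.U,
            "a_star": self.a_star.tolist(),
        }


def summarize(B, s) -> AutonomousSummary:
    """Compute the full set of autonomous equilibrium quantities."""
    B = np.asarray(B, dtype=float)
    s = np.asarray(s, dtype=float)
    x_star = equilibrium(B, s)
    r = pool_transit_times(B)
    p = transfer_probabilities(B)
    beta = s / s.sum()
    eta = x_star / x_star.sum()
    a_star, M = equilibrium_mean_ages(B, s)
    return AutonomousSummary(
        x_star=x_star, r=r, p=p, beta=beta, eta=eta,
        R=float(r @ beta), M=M, U=turnover_time(B, s), a_star=a_star)
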