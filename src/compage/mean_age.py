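"""The mean-age ODE and nonautonomous transit times.

The mean age abar_i(t) of the mass in pool i (first moment of its age
density) satisfies, along any mass solution x(t) with positive entries,
the ordinary differential equation

    d(abar_i)/dt = g_i(t, x, abar)
                 = 1 + [ sum_j (abar_j - abar_i) b_ij(t) x_j
                         - abar_i s_i(t) ] / x_i ,

so full age distributions are never needed to track mean ages.  Coupled
with the mass equation this forms a 2d-dimensional skew-product system:
x drives abar but not conversely.  From a solution (x, abar) the two
system-level summaries are

    R_t = sum_i abar_i x_i c_i / sum_i x_i c_i,  c_i = sum_j b_ji(t),
    M_t = sum_i abar_i x_i / sum_i x_i,

the mean age of mass leaving the system at time t (transit time) and
the mean age of mass currently in the system.  -c_i x_i is the external
loss flux from pool i, so R_t is the loss-flux-weighted mean age; the
formula is used exactly as stated and is invariant to flipping the sign
of all weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import autonomous
from .core_model import CompartmentalSystem, _DEFAULT_SOLVER, solve_mass

__all__ = [
    "AgeTrajectory",
    "mean_age_rhs",
    "age_coefficient_matrix",
    "solve_skew_product",
    "transit_time_series",
    "mean_age_series",
    "frozen_quantities",
    "equilibrium_initialization",
]

MASS_FLOOR_FRACTION = 1e-12


def _check_positive_mass(x: np.ndarray, floor: float) -> None:
    bad = np.flatnonzero(x <= floor)
    if bad.size:
        raise ValueError(
            f"mass of pool(s) {[int(i) + 1 for i in bad]} at or below the positivity "
            f"floor {floor:.3e}; the mean-age equation requires strictly positive mass")


def mean_age_rhs(system: CompartmentalSystem, t: float, x, abar,
                 floor: float = 0.0) -> np.ndarray:
    """Right-hand side g(t, x, abar) of the mean-age equation.

    Vanishes at an autonomous equilibrium (x*, abar*); equals (1,...,1)
    whenever all mean ages are zero (brand-new mass ages at unit rate).
    """
    x = np.asarray(x, dtype=float)
    abar = np.asarray(abar, dtype=float)
    _check_positive_mass(x, floor)
    B = system.B_at(t)
    s = system.s_at(t)
    mixing = (B * x[None, :]) @ abar - abar * (B @ x)  # sum_j (abar_j - abar_i) b_ij x_j
    return 1.0 + (mixing - abar * s) / x


def age_coefficient_matrix(system: CompartmentalSystem, t: float, x) -> np.ndarray:
    """Coefficient matrix A(t, x) of the linear form of the age equation.

    Along a fixed mass solution the age equation is linear:
    d(abar)/dt = A(t, x(t)) abar + (1,...,1)^T, with
    A = X^{-1} (B .* x_row  -  diag(s + offdiag-row-sums of B .* x_row)),
    X = diag(x).  At an autonomous equilibrium A reduces to
    (X*)^{-1} B X*.
    """
    x = np.asarray(x, dtype=float)
    _check_positive_mass(x, 0.0)
    B = system.B_at(t)
    s = system.s_at(t)
    W = B * x[None, :]                       # b_ij x_j
    A = W.copy()
    off_row = W.sum(axis=1) - np.diag(W)     # sum_{j != i} b_ij x_j
    np.fill_diagonal(A, -s - off_row)
    return A / x[:, None]


@dataclass
class AgeTrajectory:
    """Joint mass/mean-age trajectory with derived transit-time series."""

    times: np.ndarray
    x: np.ndarray          # (n, d) masses
    abar: np.ndarray       # (n, d) mean ages
    R: np.ndarray          # (n,) transit time, NaN where output flux is zero
    M: np.ndarray          # (n,) mean age of mass in the system
    labels: Sequence[str] | None = None

    @property
    def d(self) -> int:
        return self.x.shape[1]

    def to_frame(self) -> pd.DataFrame:
        names = self.labels or [f"{i+1}" for i in range(self.d)]
        df = pd.DataFrame({"t": self.times})
        for k, nm in enumerate(names):
            df[f"x_{nm}"] = self.x[:, k]
        for k, nm in enumerate(names):
            df[f"abar_{nm}"] = self.abar[:, k]
        df["R_t"] = self.R
        df["M_t"] = self.M
        return df

    def to_csv(self, path) -> None:
        # missing transit times (zero output flux) become empty cells
        self.to_frame().to_csv(path, index=False, na_rep="")


def transit_time_series(system: CompartmentalSystem, times, x, abar) -> np.ndarray:
    """R_t along a trajectory: mean age weighted by external loss flux.

    Where all column sums of B(t) vanish (momentarily closed system)
    R_t is undefined and reported as NaN, never interpolated.
    """
    times = np.asarray(times, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    abar = np.atleast_2d(np.asarray(abar, dtype=float))
    out = np.empty(times.size)
    for k, t in enumerate(times):
        c = system.B_at(t).sum(axis=0)
        w = x[k] * c
        den = w.sum()
        scale = np.abs(x[k]).max() * max(np.abs(c).max(), 1e-300)
        out[k] = np.nan if abs(den) <= 1e-14 * max(scale, 1e-300) else float(
            (abar[k] @ w) / den)
    return out


def mean_age_series(times, x, abar) -> np.ndarray:
    """M_t along a trajectory: mass-weighted mean of the pool mean ages."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    abar = np.atleast_2d(np.asarray(abar, dtype=float))
    total = x.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("mean age undefined at zero total mass")
    return (abar * x).sum(axis=1) / total


def solve_skew_product(
    system: CompartmentalSystem,
    t0: float,
    x0,
    abar0,
    out_grid,
    *,
    method: str = "coupled",
    **solver_options,
) -> AgeTrajectory:
    """Integrate the coupled mass + mean-age system onto ``out_grid``.

    ``method="coupled"`` (default) integrates the full 2d-dimensional
    system in one pass so the adaptive stepper sees the coupling;
    ``method="two_pass"`` solves the mass equation first and then the
    linear age equation along its dense output (debugging aid; the two
    must agree to integration tolerance).  Integration aborts with the
    failure time if any pool mass reaches the positivity floor
    (1e-12 of the initial total mass), where the mean-age equation
    ceases to be defined.
    """
    x0 = np.asarray(x0, dtype=float)
    abar0 = np.asarray(abar0, dtype=float)
    grid = np.asarray(out_grid, dtype=float)
    d = system.d
    _check_positive_mass(x0, 0.0)
    if np.any(abar0 < 0):
        raise ValueError("initial mean ages must be nonnegative")
    floor = MASS_FLOOR_FRACTION * x0.sum()
    opts = {**_DEFAULT_SOLVER, **solver_options}

    if method == "coupled":
        def rhs(t, y):
            x, abar = y[:d], y[d:]
            B = system.B_at(t)
            s = system.s_at(t)
            xdot = B @ x + s
            xs = np.maximum(x, floor)
            mixing = (B * xs[None, :]) @ abar - abar * (B @ xs)
            adot = 1.0 + (mixing - abar * s) / xs
            return np.concatenate([xdot, adot])

        def hit_floor(t, y):
            return float(y[:d].min() - floor)
        hit_floor.terminal = True
        hit_floor.direction = -1

        sol = solve_ivp(rhs, (t0, grid[-1]), np.concatenate([x0, abar0]),
                        t_eval=grid, events=hit_floor, **opts)
        if sol.status == 1:
            raise RuntimeError(
                f"mass reached the positivity floor at t={sol.t_events[0][0]:.6g}; "
                "mean ages are undefined beyond this point")
        if not sol.success:
            raise RuntimeError(f"skew-product integration failed: {sol.message}")
        X = sol.y[:d].T.copy()
        Abar = sol.y[d:].T.copy()
        X[0], Abar[0] = x0, abar0
    elif method == "two_pass":
        sol_x = solve_ivp(lambda t, x: system.B_at(t) @ x + system.s_at(t),
                          (t0, grid[-1]), x0, dense_output=True, **opts)
        if not sol_x.success:
            raise RuntimeError(f"mass integration failed: {sol_x.message}")
        X = sol_x.sol(grid).T.copy()
        X[0] = x0

        def rhs_a(t, abar):
            x = np.maximum(sol_x.sol(t), floor)
            return age_coefficient_matrix(system, t, x) @ abar + 1.0

        sol = solve_ivp(rhs_a, (t0, grid[-1]), abar0, t_eval=grid, **opts)
        if not sol.success:
            raise RuntimeError(f"age integration failed: {sol.message}")
        Abar = sol.y.T.copy()
        Abar[0] = abar0
    else:
        raise ValueError(f"unknown method {method!r}")

    R = transit_time_series(system, grid, X, Abar)
    M = mean_age_series(grid, X, Abar)
    return AgeTrajectory(times=grid, x=X, abar=Abar, R=R, M=M, labels=system.labels)


def frozen_quantities(system: CompartmentalSystem, t: float) -> tuple[float, float]:
    """Instantaneous (R, M) of the system frozen at time t.

    Treats (B(t), s(t)) as an autonomous system in equilibrium and
    applies the closed-form transit time and mean age.  This is a
    history-blind diagnostic: for a genuinely time-dependent system its
    equilibrium assumption is not fulfilled, which is exactly the gap
    the nonautonomous R_t and M_t quantify.
    """
    summ = autonomous.summarize(system.B_at(t), system.s_at(t))
    return summ.R, summ.M


def equilibrium_initialization(system: CompartmentalSystem, t0: float
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Spin-up initial condition: (x*, abar*) of the system frozen at t0.

    The standard convention for starting a time-dependent run: hold the
    forcing at its t0 value for all earlier times and assume the system
    has reached the resulting autonomous equilibrium, with the matching
    equilibrium mean ages.
    """
    B = system.B_at(t0)
    s = system.s_at(t0)
    x_star = autonomous.equilibrium(B, s)
    abar_star, _ = autonomous.equilibrium_mean_ages(B, s)
    return x_star, abar_star
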