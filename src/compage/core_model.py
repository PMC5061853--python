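"""Nonautonomous linear compartmental systems and mass integration.

A compartmental system is the inhomogeneous linear ODE

    dx/dt = B(t) x + s(t),

where the d-by-d coefficient matrix ``B(t)`` has strictly negative
diagonal entries (total loss rates), nonnegative off-diagonal entries
(``b_ij`` is the rate of transfer from pool j to pool i) and nonpositive
column sums (no mass is created internally), and ``s(t) >= 0`` is the
external input flux.  This module defines the model object, validates
the defining sign conditions on a sampling grid, and integrates the mass
equation, its transition operator and the pullback-attracting solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp


__all__ = [
    "CompartmentalSystem",
    "Trajectory",
    "Violation",
    "validate_system",
    "mass_rhs",
    "solve_mass",
    "transition_operator",
    "transition_operators",
    "pullback_solution",
    "mass_balance_residual",
]


def _as_callable_matrix(B, d: int) -> Callable[[float], np.ndarray]:
    if callable(B):
        return B
    B = np.asarray(B, dtype=float)
    if B.shape != (d, d):
        raise ValueError(f"expected a {d}x{d} matrix, got shape {B.shape}")
    return lambda t, _B=B: _B


def _as_callable_vector(s, d: int) -> Callable[[float], np.ndarray]:
    if callable(s):
        return s
    s = np.asarray(s, dtype=float)
    if s.shape != (d,):
        raise ValueError(f"expected a length-{d} vector, got shape {s.shape}")
    return lambda t, _s=s: _s


@dataclass
class CompartmentalSystem:
    """A d-pool linear compartmental system dx/dt = B(t) x + s(t).

    Parameters
    ----------
    d
        Number of pools.
    B
        Callable ``t -> (d, d) ndarray`` of rates (1/time), or a constant
        matrix.  ``B[i, j]`` is the rate at which mass moves from pool j
        to pool i; the diagonal holds the (negative) total loss rates.
    s
        Callable ``t -> (d,) ndarray`` of input fluxes (mass/time), or a
        constant vector.
    interval
        Practical time interval ``(t_lo, t_hi)`` on which B and s may be
        evaluated.  A conceptually unbounded-below interval is marked
        with ``unbounded_below=True``; ``t_lo`` then acts as the
        practical lower bound for finite approximations.
    labels
        Optional pool names (length d).
    """

    d: int
    B: Callable[[float], np.ndarray]
    s: Callable[[float], np.ndarray]
    interval: tuple[float, float] = (0.0, np.inf)
    unbounded_below: bool = False
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.B = _as_callable_matrix(self.B, self.d)
        self.s = _as_callable_vector(self.s, self.d)
        if self.labels is not None and len(self.labels) != self.d:
            raise ValueError("labels must have length d")

    # -- evaluation helpers -------------------------------------------------
    def B_at(self, t: float) -> np.ndarray:
        B = np.asarray(self.B(t), dtype=float)
        if B.shape != (self.d, self.d):
            raise ValueError(f"B({t}) has shape {B.shape}, expected ({self.d}, {self.d})")
        return B

    def s_at(self, t: float) -> np.ndarray:
        s = np.asarray(self.s(t), dtype=float)
        if s.shape != (self.d,):
            raise ValueError(f"s({t}) has shape {s.shape}, expected ({self.d},)")
        return s

    @property
    def is_autonomous_hint(self) -> bool:
        """Cheap probe: True if B and s agree at three spread-out times."""
        lo, hi = self.interval
        hi = min(hi, lo + 100.0)
        ts = np.linspace(lo, hi, 3)
        B0, s0 = self.B_at(ts[0]), self.s_at(ts[0])
        return all(
            np.array_equal(B0, self.B_at(t)) and np.array_equal(s0, self.s_at(t))
            for t in ts[1:]
        )

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_constant(
        cls,
        B,
        s,
        interval: tuple[float, float] = (0.0, np.inf),
        labels: Sequence[str] | None = None,
    ) -> "CompartmentalSystem":
        B = np.asarray(B, dtype=float)
        d = B.shape[0]
        return cls(d=d, B=B, s=np.asarray(s, dtype=float), interval=interval,
                   unbounded_below=True, labels=labels)

    @classmethod
    def from_tables(
        cls,
        B_table: pd.DataFrame,
        s_table: pd.DataFrame,
        labels: Sequence[str] | None = None,
    ) -> "CompartmentalSystem":
        """Build a system from sampled tables with linear interpolation.

        ``B_table`` has columns ``t, b_1_1, ..., b_d_d`` (row-major) and
        ``s_table`` has columns ``t, s_1, ..., s_d``.  Tables without a
        ``t`` column are treated as constant.  Outside the sampled range
        the value is held constant (with a warning at construction).
        """
        def interp(df: pd.DataFrame, ncols: int):
            if "t" not in df.columns:
                vals = df.iloc[0].to_numpy(dtype=float)
                return None, vals
            t = df["t"].to_numpy(dtype=float)
            if not np.all(np.diff(t) > 0):
                raise ValueError("table time column must be strictly increasing")
            Y = df.drop(columns="t").to_numpy(dtype=float)
            if Y.shape[1] != ncols:
                raise ValueError(f"expected {ncols} value columns, got {Y.shape[1]}")
            return (t, Y), None

        nb = len([c for c in B_table.columns if c != "t"])
        d = int(round(np.sqrt(nb)))
        if d * d != nb:
            raise ValueError("B table must have d*d value columns")

        bi, bconst = interp(B_table, d * d)
        si, sconst = interp(s_table, d)

        if bi is not None or si is not None:
            warnings.warn(
                "table-defined coefficients are held constant outside the "
                "sampled time range", stacklevel=2)

        def make_B():
            if bconst is not None:
                M = bconst.reshape(d, d)
                return lambda t: M
            tb, Yb = bi
            def B(t):
                row = np.array([np.interp(t, tb, Yb[:, k]) for k in range(d * d)])
                return row.reshape(d, d)
            return B

        def make_s():
            if sconst is not None:
                v = sconst
                return lambda t: v
            ts, Ys = si
            return lambda t: np.array([np.interp(t, ts, Ys[:, k]) for k in range(d)])

        lo = -np.inf if bi is None and si is None else min(
            x[0][0] for x in (bi, si) if x is not None)
        hi = np.inf if bi is None and si is None else max(
            x[0][-1] for x in (bi, si) if x is not None)
        if not np.isfinite(lo):
            lo = 0.0
        return cls(d=d, B=make_B(), s=make_s(), interval=(float(lo), float(hi)),
                   unbounded_below=(bi is None and si is None), labels=labels)


@dataclass
class Trajectory:
    """Mass trajectory on a strictly increasing time grid."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, d)
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("time grid must be strictly increasing")
        if self.states.shape[0] != self.times.size:
            raise ValueError("states and times disagree in length")

    @property
    def d(self) -> int:
        return self.states.shape[1]

    def total_mass(self) -> np.ndarray:
        return self.states.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = self.labels or [f"x_{i+1}" for i in range(self.d)]
        df = pd.DataFrame(self.states, columns=list(cols))
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class Violation:
    """One violated model condition at a sampled time."""

    condition: str  # "diagonal", "offdiagonal", "column_sum", "input_sign"
    t: float
    i: int | None
    j: int | None
    value: float


def validate_system(
    system: CompartmentalSystem,
    sample_grid,
    tol: float = 1e-10,
) -> list[Violation]:
    """Check the defining sign conditions of a compartmental system.

    At every grid point: diagonal of B strictly negative, off-diagonals
    nonnegative, column sums <= 0, inputs >= 0 — each within ``tol``.
    Returns a list of violations (empty iff all conditions hold).  An
    input that is identically zero over the whole grid is reported as a
    single warning-level violation ("input_sign" with i=j=None), since
    the stability theory concerns the homogeneous part only.

    Raises
    ------
    ValueError
        If B(t) or s(t) contains non-finite entries at a sampled time
        (a hard error distinct from a sign-condition violation).
    """
    grid = np.asarray(sample_grid, dtype=float)
    lo, hi = system.interval
    if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
        raise ValueError("sample grid extends outside the system interval")

    out: list[Violation] = []
    any_input = False
    for t in grid:
        B = system.B_at(t)
        s = system.s_at(t)
        if not (np.all(np.isfinite(B)) and np.all(np.isfinite(s))):
            raise ValueError(f"non-finite coefficients at t={t}")
        diag = np.diag(B)
        for i in np.flatnonzero(diag >= -tol):
            out.append(Violation("diagonal", float(t), int(i), int(i), float(diag[i])))
        off = B - np.diag(diag)
        for i, j in zip(*np.nonzero(off < -tol)):
            out.append(Violation("offdiagonal", float(t), int(i), int(j), float(B[i, j])))
        colsum = B.sum(axis=0)
        for j in np.flatnonzero(colsum > tol):
            out.append(Violation("column_sum", float(t), None, int(j), float(colsum[j])))
        for i in np.flatnonzero(s < -tol):
            out.append(Violation("input_sign", float(t), int(i), None, float(s[i])))
        any_input = any_input or np.any(s > tol)
    if not any_input:
        out.append(Violation("input_sign", float(grid[0]), None, None, 0.0))
    return out


def mass_rhs(system: CompartmentalSystem, t: float, x) -> np.ndarray:
    """Right-hand side B(t) x + s(t) of the mass equation."""
    x = np.asarray(x, dtype=float)
    if x.shape != (system.d,):
        raise ValueError(f"x has shape {x.shape}, expected ({system.d},)")
    return system.B_at(t) @ x + system.s_at(t)


_DEFAULT_SOLVER = dict(method="LSODA", rtol=1e-8, atol=1e-10)


def solve_mass(
    system: CompartmentalSystem,
    t0: float,
    x0,
    out_grid,
    *,
    check_positivity: bool = True,
    positivity_tol: float = 1e-8,
    **solver_options,
) -> Trajectory:
    """Integrate dx/dt = B(t) x + s(t) from ``x(t0) = x0`` onto ``out_grid``.

    Uses an adaptive implicit-capable integrator (LSODA by default,
    rtol=1e-8, atol=1e-10); pool rates spanning several orders of
    magnitude make the mass equation mildly stiff.  The first output
    state equals ``x0`` exactly.  Negative excursions beyond
    ``positivity_tol`` are warned about but never clamped.
    """
    x0 = np.asarray(x0, dtype=float)
    grid = np.asarray(out_grid, dtype=float)
    if abs(grid[0] - t0) > 0:
        raise ValueError("out_grid must start at t0")
    opts = {**_DEFAULT_SOLVER, **solver_options}
    sol = solve_ivp(
        lambda t, x: system.B_at(t) @ x + system.s_at(t),
        (t0, grid[-1]), x0, t_eval=grid, **opts)
    if not sol.success:
        raise RuntimeError(f"mass integration failed near t={sol.t[-1] if sol.t.size else t0}: "
                           f"{sol.message}")
    states = sol.y.T.copy()
    states[0] = x0
    if check_positivity and np.any(x0 >= 0):
        worst = states.min()
        if worst < -positivity_tol * max(1.0, abs(x0).sum()):
            warnings.warn(f"mass trajectory dips to {worst:.3e} below zero", stacklevel=2)
    return Trajectory(times=grid, states=states, labels=system.labels)


def transition_operators(
    system: CompartmentalSystem,
    t0: float,
    out_grid,
    **solver_options,
) -> np.ndarray:
    """Transition operators Phi(t, t0) of dx/dt = B(t) x for each grid time.

    Solves the d*d matrix ODE once; returns shape ``(len(out_grid), d, d)``.
    ``Phi(t0, t0)`` is the identity to machine precision.
    """
    d = system.d
    grid = np.asarray(out_grid, dtype=float)
    opts = {**_DEFAULT_SOLVER, **solver_options}

    def rhs(t, y):
        return (system.B_at(t) @ y.reshape(d, d)).ravel()

    sol = solve_ivp(rhs, (t0, grid[-1]), np.eye(d).ravel(), t_eval=grid, **opts)
    if not sol.success:
        raise RuntimeError(f"transition-operator integration failed: {sol.message}")
    out = sol.y.T.reshape(-1, d, d).copy()
    if abs(grid[0] - t0) == 0:
        out[0] = np.eye(d)
    return out


def transition_operator(
    system: CompartmentalSystem, t: float, t0: float, **solver_options
) -> np.ndarray:
    """Transition operator Phi(t, t0) with t >= t0."""
    if t < t0:
        raise ValueError("transition operator requires t >= t0")
    if t == t0:
        return np.eye(system.d)
    return transition_operators(system, t0, [t0, t], **solver_options)[-1]


def pullback_solution(
    system: CompartmentalSystem,
    t: float,
    burn_in: float,
    x_init=None,
    *,
    extend: str = "error",
    doubling_check: bool = True,
    return_info: bool = False,
    **solver_options,
):
    """Approximate the pullback-attracting solution nu(t).

    nu(t) is the distinguished bounded solution obtained by starting
    ever further in the past; it generalises the stable equilibrium to
    time-dependent systems.  The approximation integrates from
    ``t - burn_in`` with initial state ``x_init`` (default 0) and, when
    ``doubling_check`` is on, repeats from ``t - 2*burn_in`` and reports
    the difference — small under exponential stability.

    ``extend`` controls what happens when the burn-in reaches before the
    practical lower bound: ``"error"`` raises, ``"freeze"`` holds B and
    s at their lower-bound values for earlier times.
    """
    lo, _ = system.interval
    if x_init is None:
        x_init = np.zeros(system.d)
    x_init = np.asarray(x_init, dtype=float)

    def starting(b):
        t_start = t - b
        if t_start < lo and not system.unbounded_below:
            if extend == "error":
                raise ValueError(
                    f"burn-in {b} reaches before the interval lower bound {lo}; "
                    "pass extend='freeze' to hold coefficients constant there")
            if extend != "freeze":
                raise ValueError(f"unknown extension mode {extend!r}")
            frozen = CompartmentalSystem(
                d=system.d,
                B=lambda u: system.B_at(max(u, lo)),
                s=lambda u: system.s_at(max(u, lo)),
                interval=(t_start, system.interval[1]),
                labels=system.labels)
            return frozen, t_start
        return system, t_start

    def run(b):
        sys_b, t_start = starting(b)
        traj = solve_mass(sys_b, t_start, x_init, [t_start, t],
                          check_positivity=False, **solver_options)
        return traj.states[-1]

    nu = run(burn_in)
    info = {"burn_in": burn_in}
    if doubling_check:
        nu2 = run(2.0 * burn_in)
        info["doubling_diff"] = float(np.max(np.abs(nu2 - nu)))
        nu = nu2
    if return_info:
        return nu, info
    return nu


def mass_balance_residual(system: CompartmentalSystem, traj: Trajectory) -> float:
    """Max mass-balance residual along a trajectory.

    Compares the numerically differentiated total mass with the flux
    balance  d/dt sum_i x_i = sum_i s_i(t) + sum_j (sum_i b_ij(t)) x_j(t).
    The finite-difference error is O(h^2) in the grid spacing, so the
    residual should be judged against that scale, not solver tolerance.
    """
    total = traj.total_mass()
    dtot = np.gradient(total, traj.times)
    flux = np.array([
        system.s_at(t).sum() + system.B_at(t).sum(axis=0) @ x
        for t, x in zip(traj.times, traj.states)
    ])
    # endpoints of np.gradient are first-order; compare interior only
    return float(np.max(np.abs(dtot[1:-1] - flux[1:-1])))
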