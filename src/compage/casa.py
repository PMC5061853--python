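"""Nine-pool terrestrial carbon-cycle model (modified CASA) under CO2 forcing.

Pools 1-3 are plant carbon (leaves, roots, wood), 4-6 litter and 7-9
soil organic matter.  Rising atmospheric CO2 drives the system two
ways: it fertilises the carbon input flux s(t) into the plant pools,
and it raises the land surface temperature, which accelerates litter
and soil decomposition through a Q10-style multiplier xi applied to the
loss-rate entries of B(t).  Time t is in years since 1850; the standard
scenario runs to t = 650 (year 2500).

The forcing chain is

    x_a(t)  : atmospheric CO2 (ppm), logistic growth 285 -> 1715 ppm
              at rate 0.0305 / yr ("logistic" mode; a "verbatim"
              alternative form is retained for comparison — it starts
              at 1715 ppm and is documented as inconsistent with the
              285 ppm baseline of the rest of the forcing chain),
    T_s     = 15 + (sigma / ln 2) ln(x_a / 285)          (deg C),
    Gamma   = 42.7 + 1.68 (T_s - 25) + 0.012 (T_s - 25)^2,
    beta    = 3 rho x_a Gamma / ((rho x_a - Gamma)(rho x_a + 2 Gamma)),
    s_i(t)  = f_i alpha s0 (1 + beta ln(x_a / 285)),  i in {1, 2, 3},
    xi(T_s) = xi_b^(0.1 T_s - 2)                       (= 1 at 20 C).

xi multiplies the litter diagonal rates b44, b55, b66 and every entry
of the soil rows 7-9; the plant rows and the litter-input entries
(b41, b42, b51, b52, b63) are temperature-independent.  The absolute
input scale s0 and the temperature-sensitivity base xi_b are free
parameters (ages and transit times are provably invariant to s0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_model import CompartmentalSystem, validate_system
from .mean_age import (AgeTrajectory, equilibrium_initialization, frozen_quantities,
                       solve_skew_product)

__all__ = [
    "CasaParameters",
    "CASA_COEFFICIENTS",
    "co2_forcing",
    "surface_temperature",
    "gamma_star",
    "co2_sensitivity",
    "input_flux",
    "xi",
    "build_casa_system",
    "run_casa_scenario",
    "CasaRun",
]

CO2_BASELINE_PPM = 285.0
CO2_CAPACITY_PPM = 1715.0
CO2_RATE = 0.0305  # 1/yr

#: the 24 published transfer/loss coefficients (1/yr), 1-based (i, j) keys
CASA_COEFFICIENTS: dict[tuple[int, int], float] = {
    (1, 1): -0.67, (2, 2): -0.2, (3, 3): -0.04,
    (4, 1): 0.5092, (4, 2): 0.0260, (4, 4): -2.5,
    (5, 1): 0.1608, (5, 2): 0.1740, (5, 5): -0.4,
    (6, 3): 0.04, (6, 6): -0.25,
    (7, 4): 1.1250, (7, 5): 0.1530, (7, 6): 0.06, (7, 7): -0.7,
    (7, 8): 0.0103, (7, 9): 0.0002,
    (8, 5): 0.042, (8, 6): 0.07, (8, 7): 0.3525, (8, 8): -0.023,
    (9, 7): 0.0045, (9, 8): 0.0001, (9, 9): -0.0004,
}

POOL_LABELS = ["leaves", "roots", "wood",
               "litter_metabolic", "litter_structural", "litter_cwd",
               "soil_fast", "soil_slow", "soil_passive"]

#: entries multiplied by xi(T_s): litter diagonals plus all soil rows
_XI_SCALED = {(4, 4), (5, 5), (6, 6)} | {
    (i, j) for i in (7, 8, 9) for j in range(1, 10)}


@dataclass
class CasaParameters:
    """Tunable parameters of the CASA scenario.

    ``b89`` (soil-slow -> soil-fast... strictly: rate into pool 8 from
    pool 9) appears in the model structure but has no published value;
    the default 0 keeps column 9's sum nonpositive (values above 0.0002
    would violate the compartmental sign conditions).  ``s0`` is the
    baseline gross input scale in arbitrary mass units per year; all
    age and transit-time outputs are invariant to it.  ``xi_b`` is the
    Q10-type base of the temperature multiplier.
    """

    Ts0: float = 15.0            # mean land surface temperature in 1850 (C)
    sigma: float = 4.5           # warming per CO2 doubling (C)
    f: tuple = (0.33, 0.33, 0.33)  # input allocation to pools 1-3
    alpha: float = 0.5           # fraction of GPP remaining after respiration
    rho: float = 0.65            # intracellular / ambient CO2 ratio
    s0: float = 1.0              # gross input scale (mass / yr)
    xi_b: float = 2.0            # temperature-sensitivity base
    b89: float = 0.0             # unpublished coefficient, <= 0.0002
    co2_mode: str = "logistic"   # or "verbatim"

    def coefficients(self) -> dict[tuple[int, int], float]:
        b = dict(CASA_COEFFICIENTS)
        b[(8, 9)] = self.b89
        return b


def co2_forcing(t, mode: str = "logistic"):
    """Atmospheric CO2 (ppm) at t years since 1850.

    ``"logistic"`` (default): logistic growth from 285 ppm toward a
    1715 ppm carrying capacity at rate 0.0305/yr, monotone increasing.
    ``"verbatim"``: the alternative closed form
    1715 exp(0.0305 t / (1715 + exp(0.0305 t) - 1)), which evaluates to
    1715 ppm at t = 0 and is retained only for comparison.
    """
    t = np.asarray(t, dtype=float)
    e = np.exp(CO2_RATE * t)
    if mode == "logistic":
        out = (CO2_CAPACITY_PPM * CO2_BASELINE_PPM * e
               / (CO2_CAPACITY_PPM + CO2_BASELINE_PPM * (e - 1.0)))
    elif mode == "verbatim":
        out = CO2_CAPACITY_PPM * np.exp(CO2_RATE * t / (CO2_CAPACITY_PPM + e - 1.0))
    else:
        raise ValueError(f"unknown co2 mode {mode!r}")
    return out if out.ndim else float(out)


def surface_temperature(x_a, Ts0: float = 15.0, sigma: float = 4.5):
    """Land surface temperature (C): Ts0 + (sigma / ln 2) ln(x_a / 285)."""
    x_a = np.asarray(x_a, dtype=float)
    if np.any(x_a <= 0):
        raise ValueError("CO2 concentration must be positive")
    out = Ts0 + (sigma / np.log(2.0)) * np.log(x_a / CO2_BASELINE_PPM)
    return out if out.ndim else float(out)


def gamma_star(T_s):
    """CO2 compensation point Gamma = 42.7 + 1.68 (T_s - 25) + 0.012 (T_s - 25)^2."""
    T = np.asarray(T_s, dtype=float)
    out = 42.7 + 1.68 * (T - 25.0) + 0.012 * (T - 25.0) ** 2
    return out if out.ndim else float(out)


def co2_sensitivity(x_a: float, T_s: float, rho: float = 0.65) -> float:
    """Fertilisation sensitivity beta of the input flux to CO2.

    beta = 3 rho x_a Gamma / ((rho x_a - Gamma)(rho x_a + 2 Gamma)).
    Raises within 1e-6 of either pole (nonphysical regime).
    """
    G = gamma_star(T_s)
    rx = rho * x_a
    if abs(rx - G) < 1e-6 or abs(rx + 2.0 * G) < 1e-6:
        raise ValueError("CO2 sensitivity evaluated at a pole of the formula")
    return float(3.0 * rx * G / ((rx - G) * (rx + 2.0 * G)))


def xi(T_s, xi_b: float = 2.0):
    """Decomposition-rate multiplier xi = xi_b^(0.1 T_s - 2); xi(20 C) = 1."""
    if xi_b <= 0:
        raise ValueError("xi base must be positive")
    T = np.asarray(T_s, dtype=float)
    out = xi_b ** (0.1 * T - 2.0)
    return out if out.ndim else float(out)


def input_flux(t, params: CasaParameters | None = None) -> np.ndarray:
    """Carbon input flux s(t): pools 1-3 only.

    s_i = f_i alpha s0 (1 + beta(x_a, T_s) ln(x_a / 285)) for i in
    {1, 2, 3}; zero for the litter and soil pools.
    """
    p = params or CasaParameters()
    x_a = co2_forcing(t, p.co2_mode)
    T_s = surface_temperature(x_a, p.Ts0, p.sigma)
    beta = co2_sensitivity(x_a, T_s, p.rho)
    scale = p.alpha * p.s0 * (1.0 + beta * np.log(x_a / CO2_BASELINE_PPM))
    s = np.zeros(9)
    s[:3] = np.asarray(p.f) * scale
    return s


def build_casa_system(params: CasaParameters | None = None) -> CompartmentalSystem:
    """Assemble the 9-pool system with its published sparsity and xi placement.

    Raises at construction if the parameter set violates the
    compartmental sign conditions (e.g. b89 > 0.0002 makes column 9's
    sum positive for every xi > 0).
    """
    p = params or CasaParameters()
    coeff = p.coefficients()

    base = np.zeros((9, 9))
    mask = np.zeros((9, 9), dtype=bool)
    for (i, j), v in coeff.items():
        base[i - 1, j - 1] = v
        mask[i - 1, j - 1] = (i, j) in _XI_SCALED

    # the column sum of B(t) splits into a xi-scaled and an unscaled
    # part; both must be nonpositive for the sign conditions to hold
    # for every xi > 0, so the check is temperature-independent
    for j in range(9):
        scaled = base[mask[:, j], j].sum()
        unscaled = base[~mask[:, j], j].sum()
        if scaled > 1e-12 or unscaled > 1e-12:
            raise ValueError(
                f"column {j + 1} of the CASA matrix has a positive partial sum "
                f"(xi-scaled {scaled:.4g}, unscaled {unscaled:.4g}); the parameter "
                "set violates the compartmental sign conditions")

    def B(t):
        x_a = co2_forcing(t, p.co2_mode)
        T_s = surface_temperature(x_a, p.Ts0, p.sigma)
        x = xi(T_s, p.xi_b)
        M = base.copy()
        M[mask] *= x
        return M

    return CompartmentalSystem(
        d=9, B=B, s=lambda t: input_flux(t, p),
        interval=(0.0, 650.0), unbounded_below=False, labels=POOL_LABELS)


@dataclass
class CasaRun:
    """Result of a CASA scenario run."""

    params: CasaParameters
    trajectory: AgeTrajectory
    R_frozen: np.ndarray
    M_frozen: np.ndarray
    x_a: np.ndarray
    T_s: np.ndarray
    xi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = self.trajectory.to_frame()
        df.insert(1, "year", 1850.0 + df["t"])
        df["R_frozen"] = self.R_frozen
        df["M_frozen"] = self.M_frozen
        df["xa"] = self.x_a
        df["Ts"] = self.T_s
        df["xi"] = self.xi
        return df

    def to_csv(self, path, sidecar: str | None = None) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="")
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump(asdict(self.params), fh, indent=2)


def run_casa_scenario(
    params: CasaParameters | None = None,
    t_end: float = 650.0,
    out_grid=None,
    validate: bool = True,
    **solver_options,
) -> CasaRun:
    """Spin up at t = 0 and run the climate-change scenario to ``t_end``.

    Initialisation freezes the forcing at its t = 0 value and starts
    from the equilibrium mass and equilibrium mean ages of the
    resulting autonomous system (so M at t = 0 equals the frozen-
    equilibrium mean age by construction).  Attaches the nonautonomous
    R_t and M_t and, for comparison, the history-blind frozen R and M
    computed from (B(t), s(t)) at each output time.
    """
    p = params or CasaParameters()
    system = build_casa_system(p)
    if validate:
        bad = [v for v in validate_system(system, np.linspace(0, t_end, 201))
               if v.condition != "input_sign"]
        if bad:
            raise ValueError(f"CASA system fails validation: {bad[:3]}")
    if out_grid is None:
        out_grid = np.linspace(0.0, t_end, int(t_end) + 1)
    out_grid = np.asarray(out_grid, dtype=float)

    x0, abar0 = equilibrium_initialization(system, 0.0)
    traj = solve_skew_product(system, 0.0, x0, abar0, out_grid, **solver_options)

    RM = np.array([frozen_quantities(system, t) for t in out_grid])
    x_a = co2_forcing(out_grid, p.co2_mode)
    T_s = surface_temperature(x_a, p.Ts0, p.sigma)
    return CasaRun(params=p, trajectory=traj,
                   R_frozen=RM[:, 0], M_frozen=RM[:, 1],
                   x_a=np.asarray(x_a), T_s=np.asarray(T_s),
                   xi=np.asarray(xi(T_s, p.xi_b)))
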