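"""Random compartmental systems and named worked-example fixtures.

The generator draws sparse random transfer matrices and then fixes the
diagonal so that a requested set of structural conditions is guaranteed
by construction:

``"compartmental"``
    the defining sign conditions (negative diagonal, nonnegative
    off-diagonals, nonpositive column sums) with a positive slack;
``"mass_stable"``
    additionally strict row diagonal dominance of every diagonal block
    of the lower block triangular form, with a uniform margin — the
    sufficient criterion for exponential stability of the mass system;
``"age_stable"``
    additionally positive input into every first-block pool and, for
    every pool of a later block, a donor rate from an earlier block
    bounded away from zero — the extra conditions under which the
    mean-age system is exponentially stable.

Time dependence is a smooth multiplicative factor in [0.7, 1.3] applied
to the whole matrix (and an independent one to the input vector), which
preserves every enforced inequality up to a known rescaling of the
margin; each generated system re-verifies its own contract by sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import CompartmentalSystem, validate_system
from .stability import block_structure, check_theorem_mass

__all__ = ["GeneratorSpec", "generate_system", "fixture", "FIXTURE_NAMES"]


@dataclass
class GeneratorSpec:
    """Recipe for one random compartmental system."""

    d: int
    seed: int = 0
    connectivity: float = 0.4        # edge probability
    enforce: str = "compartmental"   # "compartmental" | "mass_stable" | "age_stable"
    time_dependence: str = "constant"  # "constant" | "sinusoidal" | "interpolated"
    rate_scale: float = 1.0
    margin: float = 0.1              # slack / dominance margin, x rate_scale


def _modulator(kind: str, rng: np.random.Generator):
    """A smooth positive factor t -> [0.7, 1.3]."""
    if kind == "constant":
        return lambda t: 1.0
    if kind == "sinusoidal":
        amp = rng.uniform(0.1, 0.3)
        omega = rng.uniform(0.3, 1.5)
        phase = rng.uniform(0.0, 2 * np.pi)
        return lambda t: 1.0 + amp * np.sin(omega * t + phase)
    if kind == "interpolated":
        knots_t = np.linspace(0.0, 100.0, 12)
        knots_v = rng.uniform(0.7, 1.3, size=12)
        return lambda t: float(np.interp(np.clip(t, 0.0, 100.0), knots_t, knots_v))
    raise ValueError(f"unknown time dependence {kind!r}")


def generate_system(spec: GeneratorSpec) -> CompartmentalSystem:
    """Draw a random system satisfying the requested condition set.

    Deterministic under ``spec.seed``.  Raises if the spec is
    structurally infeasible after a bounded number of retries.
    """
    if spec.enforce not in ("compartmental", "mass_stable", "age_stable"):
        raise ValueError(f"unknown condition set {spec.enforce!r}")
    rng = np.random.default_rng(spec.seed)
    d, sc = spec.d, spec.rate_scale
    marg = spec.margin * sc

    for _attempt in range(20):
        Off = np.where(rng.random((d, d)) < spec.connectivity,
                       rng.uniform(0.1, 1.0, (d, d)) * sc, 0.0)
        np.fill_diagonal(Off, 0.0)

        s = rng.uniform(0.1, 1.0, d) * sc * (rng.random(d) < 0.7)
        if not np.any(s > 0):
            s[rng.integers(d)] = rng.uniform(0.5, 1.0) * sc

        if spec.enforce in ("mass_stable", "age_stable"):
            probe = CompartmentalSystem(
                d=d, B=Off - np.diag(Off.sum(axis=0) + marg), s=s,
                interval=(0.0, 100.0))
            blocks = block_structure(probe, [0.0]).blocks

            if spec.enforce == "age_stable":
                earlier: list[int] = list(blocks[0])
                for block in blocks[1:]:
                    for i in block:
                        if Off[i, earlier].max(initial=0.0) < marg:
                            j = int(rng.choice(earlier))
                            Off[i, j] = rng.uniform(1.0, 2.0) * marg
                    earlier.extend(block)
                s[blocks[0]] = np.maximum(s[blocks[0]], rng.uniform(1.0, 2.0, len(blocks[0])) * marg)
                probe = CompartmentalSystem(
                    d=d, B=Off - np.diag(Off.sum(axis=0) + marg), s=s,
                    interval=(0.0, 100.0))
                blocks = block_structure(probe, [0.0]).blocks

            # diagonal must dominate both the column (sign conditions)
            # and the within-block row (stability criterion)
            diag = np.empty(d)
            for block in blocks:
                idx = np.array(block, dtype=int)
                for i in idx:
                    row_in_block = Off[i, idx].sum()
                    diag[i] = -(max(Off[:, i].sum(), row_in_block) + marg)
            B0 = Off + np.diag(diag)
        else:
            B0 = Off - np.diag(Off.sum(axis=0) + marg * rng.uniform(0.5, 1.5, d))

        fB = _modulator(spec.time_dependence, rng)
        fs = _modulator(spec.time_dependence, rng)
        system = CompartmentalSystem(
            d=d,
            B=(lambda t, _B=B0, _f=fB: _B * _f(t)),
            s=(lambda t, _s=s, _f=fs: _s * _f(t)),
            interval=(0.0, 100.0),
            unbounded_below=(spec.time_dependence == "constant"))

        grid = np.linspace(0.0, 100.0, 41)
        bad = [v for v in validate_system(system, grid) if v.condition != "input_sign"]
        if bad:
            continue
        if spec.enforce in ("mass_stable", "age_stable"):
            if check_theorem_mass(system, grid).delta_estimate <= 0:
                continue
        return system

    raise RuntimeError(f"could not generate a system for spec {spec}")


def _example_cascade_constant() -> CompartmentalSystem:
    B = np.array([[-1.0, 0.0], [0.5, -2.0]])
    s = np.array([0.0, 1.0])
    return CompartmentalSystem.from_constant(B, s)


def _example_cascade_timevarying() -> CompartmentalSystem:
    def B(t):
        return np.array([[-(1.0 + 0.25 * np.sin(t)), 0.0],
                         [0.5, -(2.0 + 0.5 * np.cos(t))]])

    def s(t):
        return np.array([0.0, 1.0 + 0.5 * np.sin(0.5 * t)])

    return CompartmentalSystem(d=2, B=B, s=s, interval=(0.0, np.inf),
                               unbounded_below=True)


FIXTURE_NAMES = ("two_pool_a", "two_pool_b", "cascade_constant",
                 "cascade_timevarying", "one_pool", "casa_default")


def fixture(name: str) -> CompartmentalSystem:
    """Named worked-example systems.

    ``"two_pool_a"``: B = [[-1, 2], [0.5, -2]], s = (1, 0) — mass can
    leave only through pool 1; its transit time R = 2.5 is smaller than
    its mean age M = 2.6.
    ``"two_pool_b"``: B = [[-1, 1], [1, -2]], s = (1, 0) — mass leaves
    only through pool 2; here R = 3 exceeds M = 8/3.
    ``"cascade_constant"`` / ``"cascade_timevarying"``: explicitly
    solvable feed-forward two-pool chains (no feedback loop).
    ``"one_pool"``: dx/dt = -x + 1, the scalar case where transit time
    and mean age coincide.
    ``"casa_default"``: the nine-pool carbon-cycle model with default
    parameters.
    """
    if name == "two_pool_a":
        return CompartmentalSystem.from_constant(
            np.array([[-1.0, 2.0], [0.5, -2.0]]), np.array([1.0, 0.0]))
    if name == "two_pool_b":
        return CompartmentalSystem.from_constant(
            np.array([[-1.0, 1.0], [1.0, -2.0]]), np.array([1.0, 0.0]))
    if name == "cascade_constant":
        return _example_cascade_constant()
    if name == "cascade_timevarying":
        return _example_cascade_timevarying()
    if name == "one_pool":
        return CompartmentalSystem.from_constant(
            np.array([[-1.0]]), np.array([1.0]))
    if name == "casa_default":
        from .casa import build_casa_system
        return build_casa_system()
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
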