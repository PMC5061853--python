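"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import numpy as np
import pytest

import compage as cp


@pytest.fixture(scope="session")
def two_pool_a():
    """Two-pool system whose only exit is pool 1 (R < M)."""
    return cp.fixture("two_pool_a")


@pytest.fixture(scope="session")
def two_pool_b():
    """Two-pool system whose only exit is pool 2 (R > M)."""
    return cp.fixture("two_pool_b")


@pytest.fixture(scope="session")
def one_pool():
    return cp.fixture("one_pool")


@pytest.fixture(scope="session")
def casa_system():
    return cp.build_casa_system()


@pytest.fixture(scope="session")
def casa_run_default():
    """Full 650-year CASA scenario with default parameters (shared)."""
    return cp.run_casa_scenario()


# --------------------------------------------------------------------------
# independent oracles (never routed through the implementation under test)

def inverse_2x2(B):
    """Cofactor inverse of a 2x2 matrix."""
    (a, b), (c, d) = np.asarray(B, dtype=float)
    det = a * d - b * c
    return np.array([[d, -b], [-c, a]]) / det


def simulate_particle_transit(B, s, n, rng):
    """Monte-Carlo residence times of n particles through the jump chain.

    Particles enter pool i with probability s_i / sum(s), stay an
    exponential sojourn with rate -b_ii, then jump to pool j with
    probability -b_ji / b_ii or exit with the remaining probability.
    Returns the n total residence times.
    """
    B = np.asarray(B, dtype=float)
    s = np.asarray(s, dtype=float)
    d = B.shape[0]
    rates = -np.diag(B)
    P = -(B.T / np.diag(B)[:, None])
    np.fill_diagonal(P, 0.0)
    exit_p = 1.0 - P.sum(axis=1)

    pool = rng.choice(d, size=n, p=s / s.sum())
    total = np.zeros(n)
    active = np.ones(n, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        total[idx] += rng.exponential(1.0 / rates[pool[idx]])
        cum = np.cumsum(np.column_stack([P[pool[idx]], exit_p[pool[idx]]]), axis=1)
        nxt = (rng.random(idx.size)[:, None] < cum).argmax(axis=1)
        exited = nxt == d
        active[idx[exited]] = False
        pool[idx[~exited]] = nxt[~exited]
    return total


def random_compartmental(rng, d=None, autonomous=True, enforce="compartmental"):
    """Draw a valid constant compartmental system via the generator.

    ``enforce="age_stable"`` guarantees every pool is reachable from the
    inputs, hence a strictly positive equilibrium (needed wherever mean
    ages are formed).
    """
    d = d or int(rng.integers(2, 9))
    spec = cp.GeneratorSpec(d=d, seed=int(rng.integers(2**31)),
                            enforce=enforce,
                            time_dependence="constant" if autonomous else "sinusoidal")
    return cp.generate_system(spec)


def assert_trajectory_sane(system, traj, balance_tol):
    """Running invariant: positivity and mass balance along a trajectory."""
    assert traj.states.min() > -1e-8 * max(1.0, traj.states.max())
    assert cp.mass_balance_residual(system, traj) < balance_tol
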