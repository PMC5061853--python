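"""The mean-age ODE, skew-product integration and R_t / M_t series."""

import numpy as np
import pytest

import compage as cp
from conftest import random_compartmental


class TestMeanAgeRhs:
    def test_vanishes_at_autonomous_equilibrium(self, two_pool_a):
        g = cp.mean_age_rhs(two_pool_a, 0.0, [2.0, 0.5], [2.5, 3.0])
        np.testing.assert_allclose(g, [0.0, 0.0], atol=1e-14)

    def test_fresh_mass_ages_at_unit_rate(self):
        rng = np.random.default_rng(1)
        system = random_compartmental(rng, d=5)
        x = rng.uniform(0.5, 2.0, 5)
        g = cp.mean_age_rhs(system, 0.0, x, np.zeros(5))
        np.testing.assert_allclose(g, np.ones(5), atol=1e-14)

    def test_one_pool_balance(self):
        one = cp.CompartmentalSystem.from_constant([[-3.0]], [0.5])
        # da/dt = 1 - (s/x) a = 1 - 0.5*2/1 = 0
        g = cp.mean_age_rhs(one, 0.0, [1.0], [2.0])
        assert abs(g[0]) < 1e-14

    def test_nonpositive_mass_is_refused(self, two_pool_a):
        with pytest.raises(ValueError, match="pool"):
            cp.mean_age_rhs(two_pool_a, 0.0, [1.0, 0.0], [0.0, 0.0])


class TestAgeCoefficientMatrix:
    def test_reduces_to_similarity_transform_at_equilibrium(self, two_pool_a):
        # at x*: A = (X*)^{-1} B X* = [[-1, 0.5], [2, -2]]
        A = cp.age_coefficient_matrix(two_pool_a, 0.0, [2.0, 0.5])
        np.testing.assert_allclose(A, [[-1.0, 0.5], [2.0, -2.0]], atol=1e-14)
        X = np.diag([2.0, 0.5])
        np.testing.assert_allclose(
            A, np.linalg.solve(X, two_pool_a.B_at(0) @ X), atol=1e-14)

    def test_linear_form_matches_nonlinear_rhs(self):
        rng = np.random.default_rng(7)
        system = random_compartmental(rng, d=4, autonomous=False)
        for _ in range(5):
            t = rng.uniform(0, 10)
            x = rng.uniform(0.2, 3.0, 4)
            abar = rng.uniform(0.0, 5.0, 4)
            A = cp.age_coefficient_matrix(system, t, x)
            np.testing.assert_allclose(
                A @ abar + 1.0, cp.mean_age_rhs(system, t, x, abar), atol=1e-12)

    def test_one_pool_scalar(self):
        one = cp.CompartmentalSystem.from_constant([[-3.0]], [0.5])
        A = cp.age_coefficient_matrix(one, 0.0, [2.0])
        assert abs(A[0, 0] - (-0.25)) < 1e-14  # -s/x


class TestSkewProduct:
    def test_equilibrium_is_a_fixed_point(self, two_pool_a):
        grid = np.linspace(0, 50, 26)
        traj = cp.solve_skew_product(two_pool_a, 0.0, [2.0, 0.5], [2.5, 3.0], grid)
        np.testing.assert_allclose(traj.x, np.tile([2.0, 0.5], (26, 1)), atol=1e-7)
        np.testing.assert_allclose(traj.abar, np.tile([2.5, 3.0], (26, 1)), atol=1e-6)

    def test_zero_ages_converge_to_equilibrium_ages(self, two_pool_a):
        grid = np.linspace(0, 50, 51)
        traj = cp.solve_skew_product(two_pool_a, 0.0, [2.0, 0.5], [0.0, 0.0], grid)
        np.testing.assert_allclose(traj.abar[-1], [2.5, 3.0], atol=1e-3)

    def test_one_pool_closed_form(self, one_pool):
        grid = np.linspace(0, 6, 61)
        traj = cp.solve_skew_product(one_pool, 0.0, [1.0], [0.0], grid)
        # with x held at 1 the age obeys da/dt = 1 - a: a(t) = 1 - e^{-t}
        np.testing.assert_allclose(traj.abar[:, 0], 1 - np.exp(-grid), atol=1e-6)
        # scalar systems: transit time and mean age are the age itself
        np.testing.assert_allclose(traj.R, traj.abar[:, 0], atol=1e-12)
        np.testing.assert_allclose(traj.M, traj.abar[:, 0], atol=1e-12)

    def test_two_pass_agrees_with_coupled(self):
        rng = np.random.default_rng(9)
        system = random_compartmental(rng, d=3, autonomous=False)
        grid = np.linspace(0, 10, 41)
        x0 = rng.uniform(0.5, 2.0, 3)
        a0 = rng.uniform(0.0, 3.0, 3)
        coupled = cp.solve_skew_product(system, 0.0, x0, a0, grid)
        twopass = cp.solve_skew_product(system, 0.0, x0, a0, grid, method="two_pass")
        np.testing.assert_allclose(coupled.abar, twopass.abar, atol=1e-6)

    def test_scale_invariance_in_input_and_mass(self):
        rng = np.random.default_rng(10)
        system = random_compartmental(rng, d=3, autonomous=False)
        grid = np.linspace(0, 15, 31)
        x0, a0 = rng.uniform(0.5, 2.0, 3), rng.uniform(0.0, 2.0, 3)
        base = cp.solve_skew_product(system, 0.0, x0, a0, grid)
        c = 7.0
        scaled_sys = cp.CompartmentalSystem(
            d=3, B=system.B, s=lambda t: c * system.s_at(t),
            interval=system.interval, unbounded_below=True)
        scaled = cp.solve_skew_product(scaled_sys, 0.0, c * x0, a0, grid)
        np.testing.assert_allclose(scaled.abar, base.abar, atol=1e-6)
        np.testing.assert_allclose(scaled.R, base.R, atol=1e-6)
        np.testing.assert_allclose(scaled.M, base.M, atol=1e-6)

    def test_bounds_on_system_mean_age(self):
        rng = np.random.default_rng(12)
        system = random_compartmental(rng, d=4, autonomous=False)
        grid = np.linspace(0, 12, 25)
        x0, a0 = rng.uniform(0.5, 2.0, 4), rng.uniform(0.0, 4.0, 4)
        traj = cp.solve_skew_product(system, 0.0, x0, a0, grid)
        assert np.all(traj.M >= traj.abar.min(axis=1) - 1e-10)
        assert np.all(traj.M <= traj.abar.max(axis=1) + 1e-10)


class TestSeries:
    def test_transit_time_weights_are_loss_fluxes(self, two_pool_a, two_pool_b):
        # only pool 1 loses mass in system a, only pool 2 in system b
        R_a = cp.transit_time_series(two_pool_a, [0.0], [[2.0, 0.5]], [[2.5, 3.0]])
        assert abs(R_a[0] - 2.5) < 1e-12
        R_b = cp.transit_time_series(two_pool_b, [0.0], [[2.0, 1.0]], [[2.5, 3.0]])
        assert abs(R_b[0] - 3.0) < 1e-12

    def test_closed_system_gives_missing_value(self):
        closed = cp.CompartmentalSystem.from_constant(
            np.array([[-1.0, 1.0], [1.0, -1.0 + 0.0]]) , np.array([1.0, 0.0]))
        # columns sum to zero: no external loss anywhere
        R = cp.transit_time_series(closed, [0.0], [[1.0, 1.0]], [[1.0, 2.0]])
        assert np.isnan(R[0])

    def test_mean_age_series_values(self, two_pool_a, two_pool_b):
        M_a = cp.mean_age_series([0.0], [[2.0, 0.5]], [[2.5, 3.0]])
        assert abs(M_a[0] - 2.6) < 1e-12
        M_b = cp.mean_age_series([0.0], [[2.0, 1.0]], [[2.5, 3.0]])
        assert abs(M_b[0] - 8.0 / 3.0) < 1e-12
        # equal pool ages collapse to that age
        M_c = cp.mean_age_series([0.0], [[1.0, 4.0]], [[1.7, 1.7]])
        assert abs(M_c[0] - 1.7) < 1e-14


class TestFrozenAndInitialization:
    def test_frozen_quantities_of_autonomous_system(self, two_pool_a):
        for t in (0.0, 13.0):
            R, M = cp.frozen_quantities(two_pool_a, t)
            assert abs(R - 2.5) < 1e-12 and abs(M - 2.6) < 1e-12

    def test_equilibrium_initialization(self, two_pool_a):
        x0, a0 = cp.equilibrium_initialization(two_pool_a, 0.0)
        np.testing.assert_allclose(x0, [2.0, 0.5], atol=1e-12)
        np.testing.assert_allclose(a0, [2.5, 3.0], atol=1e-12)

    def test_casa_initialization_is_positive_and_finite(self, casa_system):
        x0, a0 = cp.equilibrium_initialization(casa_system, 0.0)
        assert x0.shape == (9,) and a0.shape == (9,)
        assert np.all(x0 > 0) and np.all(a0 > 0)
        assert np.all(np.isfinite(x0)) and np.all(np.isfinite(a0))


class TestAutonomousConsistency:
    """Started at (x*, abar*), the nonautonomous series stay at (R, M)."""

    @pytest.mark.parametrize("seed", [100, 101, 102])
    def test_series_constant_and_equal_to_closed_forms(self, seed):
        rng = np.random.default_rng(seed)
        system = random_compartmental(rng, d=4, enforce="age_stable")
        B, s = system.B_at(0), system.s_at(0)
        summ = cp.summarize(B, s)
        grid = np.linspace(0, 30, 31)
        traj = cp.solve_skew_product(system, 0.0, summ.x_star, summ.a_star, grid,
                                     rtol=1e-11, atol=1e-12)
        np.testing.assert_allclose(traj.R, summ.R, atol=1e-8)
        np.testing.assert_allclose(traj.M, summ.M, atol=1e-8)
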