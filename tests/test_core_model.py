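"""Model validation, mass integration, transition operators, pullback."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

import compage as cp
from conftest import assert_trajectory_sane, random_compartmental


class TestValidate:
    def test_valid_two_pool_reports_nothing(self, two_pool_a):
        assert cp.validate_system(two_pool_a, np.linspace(0, 10, 11)) == []

    def test_positive_diagonal_is_reported_everywhere(self):
        bad = cp.CompartmentalSystem.from_constant(np.array([[1.0]]), np.array([1.0]))
        report = cp.validate_system(bad, np.linspace(0, 5, 7))
        assert len(report) >= 7
        assert all(v.condition in ("diagonal", "column_sum") for v in report)
        assert sum(v.condition == "diagonal" for v in report) == 7

    def test_casa_matrix_is_valid_and_plant_columns_close(self, casa_system):
        report = cp.validate_system(casa_system, np.linspace(0, 650, 41))
        assert report == []
        for t in (0.0, 325.0, 650.0):
            colsum = casa_system.B_at(t).sum(axis=0)
            # plant columns recycle everything internally: sums exactly 0
            assert np.abs(colsum[:3]).max() < 1e-15
            assert np.all(colsum[3:] < 0)

    def test_nonfinite_coefficients_are_a_hard_error(self):
        bad = cp.CompartmentalSystem(
            d=1, B=lambda t: np.array([[np.nan]]), s=lambda t: np.array([1.0]),
            interval=(0, 10))
        with pytest.raises(ValueError, match="non-finite"):
            cp.validate_system(bad, [0.0, 1.0])

    def test_zero_input_is_flagged_softly(self):
        quiet = cp.CompartmentalSystem.from_constant(
            np.array([[-1.0]]), np.array([0.0]))
        report = cp.validate_system(quiet, [0.0, 1.0])
        assert [v.condition for v in report] == ["input_sign"]


class TestMassRhs:
    @pytest.mark.parametrize("B, s, x, expected", [
        ([[-2.0]], [1.0], [0.5], [0.0]),                         # equilibrium
        ([[-1, 2], [0.5, -2]], [1, 0], [2.0, 0.5], [0.0, 0.0]),  # equilibrium
        ([[-1, 2], [0.5, -2]], [1, 0], [0.0, 0.0], [1.0, 0.0]),  # rhs = s at origin
    ])
    def test_known_values(self, B, s, x, expected):
        system = cp.CompartmentalSystem.from_constant(np.array(B, float), np.array(s, float))
        np.testing.assert_allclose(cp.mass_rhs(system, 0.0, x), expected, atol=1e-14)

    def test_dimension_mismatch(self, two_pool_a):
        with pytest.raises(ValueError):
            cp.mass_rhs(two_pool_a, 0.0, [1.0, 2.0, 3.0])


class TestSolveMass:
    def test_one_pool_closed_form(self, one_pool):
        grid = np.linspace(0, 5, 51)
        traj = cp.solve_mass(one_pool, 0.0, [0.0], grid)
        np.testing.assert_allclose(traj.states[:, 0], 1 - np.exp(-grid), atol=1e-6)
        assert traj.states[0, 0] == 0.0

    def test_cascade_matches_independent_quadrature(self):
        # feed-forward chain: x1 decays freely, x2 solved by the
        # variation-of-constants integral evaluated with scipy.quad
        system = cp.fixture("cascade_constant")
        b11, b21, b22, s2 = -1.0, 0.5, -2.0, 1.0
        grid = np.linspace(0, 4, 9)
        traj = cp.solve_mass(system, 0.0, [1.0, 0.0], grid)
        for t, (x1, x2) in zip(grid, traj.states):
            assert abs(x1 - np.exp(b11 * t)) < 1e-6
            oracle = quad(lambda u: np.exp(b22 * (t - u)) * (b21 * np.exp(b11 * u) + s2),
                          0, t)[0]
            assert abs(x2 - oracle) < 1e-6

    def test_equilibrium_is_stationary(self, two_pool_a):
        grid = np.linspace(0, 20, 21)
        traj = cp.solve_mass(two_pool_a, 0.0, [2.0, 0.5], grid)
        np.testing.assert_allclose(traj.states, np.tile([2.0, 0.5], (21, 1)), atol=1e-7)

    def test_linearity_in_input_and_initial_state(self):
        rng = np.random.default_rng(11)
        system = random_compartmental(rng, d=4)
        grid = np.linspace(0, 8, 17)
        x0 = rng.uniform(0.5, 2.0, 4)
        base = cp.solve_mass(system, 0.0, x0, grid)
        c = 3.7
        scaled_sys = cp.CompartmentalSystem(
            d=4, B=system.B, s=lambda t: c * system.s_at(t), interval=system.interval,
            unbounded_below=True)
        scaled = cp.solve_mass(scaled_sys, 0.0, c * x0, grid)
        np.testing.assert_allclose(scaled.states, c * base.states, rtol=1e-6, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_positivity_and_mass_balance(self, seed):
        rng = np.random.default_rng(seed)
        system = random_compartmental(rng, autonomous=False)
        grid = np.linspace(0, 10, 401)
        x0 = rng.uniform(0.0, 2.0, system.d)
        traj = cp.solve_mass(system, 0.0, x0, grid)
        # central differences on this grid are accurate to O(h^2) ~ 6e-4
        assert_trajectory_sane(system, traj, balance_tol=5e-3)


class TestTransitionOperator:
    def test_identity_at_equal_times(self, two_pool_a):
        np.testing.assert_allclose(
            cp.transition_operator(two_pool_a, 3.0, 3.0), np.eye(2), atol=1e-12)

    def test_scalar_exponential(self):
        one = cp.CompartmentalSystem.from_constant(np.array([[-1.0]]), np.array([1.0]))
        phi = cp.transition_operator(one, 2.5, 1.0)
        assert abs(phi[0, 0] - np.exp(-1.5)) < 1e-8

    def test_cocycle_property(self):
        rng = np.random.default_rng(3)
        spec = cp.GeneratorSpec(d=3, seed=7, enforce="compartmental",
                                time_dependence="sinusoidal")
        system = cp.generate_system(spec)
        full = cp.transition_operator(system, 2.0, 0.0)
        composed = cp.transition_operator(system, 2.0, 1.0) @ cp.transition_operator(system, 1.0, 0.0)
        np.testing.assert_allclose(full, composed, atol=1e-8)

    def test_matches_matrix_exponential_for_autonomous(self):
        rng = np.random.default_rng(21)
        for _ in range(3):
            system = random_compartmental(rng, d=4)
            B = system.B_at(0.0)
            phi = cp.transition_operator(system, 1.7, 0.0)
            np.testing.assert_allclose(phi, expm(1.7 * B), atol=1e-8)


class TestPullback:
    def test_autonomous_pullback_is_the_equilibrium(self, two_pool_a):
        nu, info = cp.pullback_solution(two_pool_a, 0.0, 60.0, return_info=True)
        np.testing.assert_allclose(nu, [2.0, 0.5], atol=1e-6)
        assert info["doubling_diff"] < 1e-6

    def test_one_pool_constant_input(self):
        one = cp.CompartmentalSystem.from_constant(np.array([[-1.0]]), np.array([1.0]))
        nu = cp.pullback_solution(one, 4.0, 50.0)
        assert abs(nu[0] - 1.0) < 1e-6

    def test_sinusoidal_input_matches_convolution_quadrature(self):
        system = cp.CompartmentalSystem(
            d=1, B=lambda t: np.array([[-1.0]]),
            s=lambda t: np.array([2.0 + np.sin(t)]),
            interval=(-np.inf, np.inf), unbounded_below=True)
        t = 2.0
        nu = cp.pullback_solution(system, t, 60.0)
        oracle = quad(lambda u: np.exp(-(t - u)) * (2.0 + np.sin(u)), t - 80, t)[0]
        assert abs(nu[0] - oracle) < 1e-6

    def test_burn_in_beyond_interval_errors_without_extension(self, casa_system):
        with pytest.raises(ValueError, match="burn-in"):
            cp.pullback_solution(casa_system, 10.0, 50.0)
        nu = cp.pullback_solution(casa_system, 10.0, 50.0, extend="freeze",
                                  doubling_check=False)
        assert nu.shape == (9,) and np.all(np.isfinite(nu))


class TestTables:
    def test_save_and_reload_roundtrip(self, tmp_path):
        spec = cp.GeneratorSpec(d=3, seed=13, enforce="compartmental",
                                time_dependence="sinusoidal")
        system = cp.generate_system(spec)
        cfg = tmp_path / "sys.json"
        cp.save_generated_system(system, cfg, n_knots=401)
        with pytest.warns(UserWarning, match="constant outside"):
            reloaded = cp.load_system(cfg)
        for t in (0.0, 7.3, 42.0):
            np.testing.assert_allclose(reloaded.B_at(t), system.B_at(t), atol=2e-3)
            np.testing.assert_allclose(reloaded.s_at(t), system.s_at(t), atol=2e-3)

    def test_constant_table_has_no_time_column(self):
        import pandas as pd
        Bt = pd.DataFrame([[-1.0, 2.0, 0.5, -2.0]],
                          columns=["b_1_1", "b_1_2", "b_2_1", "b_2_2"])
        st = pd.DataFrame([[1.0, 0.0]], columns=["s_1", "s_2"])
        system = cp.CompartmentalSystem.from_tables(Bt, st)
        np.testing.assert_allclose(system.B_at(5.0), [[-1, 2], [0.5, -2]])
        assert system.unbounded_below
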