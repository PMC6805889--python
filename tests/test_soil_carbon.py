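"""Single-pool soil carbon model: worked arithmetic, dynamics, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from agroshift.soil_carbon import (
    AreaWeights,
    SoilCarbonParams,
    area_weighted_rate,
    c_to_co2,
    fit_single_pool,
    steady_state,
    time_to_steady_state,
    trajectory,
    transition_rate,
)

# NSI-derived rotational-grass parameters used in the worked example
I_RG, K_RG, C_ARABLE = 2.54, 0.046, 43.2


class TestSteadyState:
    @pytest.mark.parametrize(
        "i, k, expected",
        [(0.0, 0.05, 0.0), (1.0, 1.0, 1.0), (I_RG, K_RG, I_RG / K_RG)],
    )
    def test_equals_i_over_k(self, i, k, expected):
        assert steady_state(i, k) == pytest.approx(expected)

    def test_printed_parameters_give_55_2(self):
        # from the printed (rounded) I and k; the published table rounds to 55.0
        assert steady_state(I_RG, K_RG) == pytest.approx(55.2, abs=0.05)

    def test_rejects_nonpositive_k(self):
        with pytest.raises(ValueError):
            steady_state(1.0, 0.0)


class TestTrajectory:
    def test_starts_at_c0_and_converges_to_steady_state(self):
        p = SoilCarbonParams(I_RG, K_RG, C_ARABLE)
        assert trajectory(p, 0.0) == pytest.approx(C_ARABLE)
        assert trajectory(p, 1e4) == pytest.approx(p.steady_state, abs=1e-6)

    def test_matches_numerical_ode_integration(self):
        p = SoilCarbonParams(I_RG, K_RG, C_ARABLE)
        ts = np.linspace(0, 50, 101)
        sol = solve_ivp(
            lambda t, c: p.input_rate - p.decay_constant * c,
            (0, 50), [C_ARABLE], t_eval=ts, max_step=0.01,
        )
        assert np.allclose(trajectory(p, ts), sol.y[0], atol=1e-4)

    def test_monotone_toward_steady_state_from_both_sides(self):
        for c0 in (30.0, 70.0):
            p = SoilCarbonParams(I_RG, K_RG, c0)
            vals = trajectory(p, np.linspace(0, 100, 50))
            diffs = np.diff(vals)
            assert np.all(diffs >= -1e-12) if c0 < p.steady_state else np.all(diffs <= 1e-12)


class TestTransitionRate:
    def test_arable_to_rotational_grass_worked_example(self):
        assert transition_rate(I_RG, K_RG, C_ARABLE) == pytest.approx(0.28, abs=0.005)

    def test_zero_at_steady_state(self):
        assert transition_rate(1.0, 0.05, 20.0) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert transition_rate(1.0, 0.1, 5.0) == pytest.approx(0.25)

    @given(
        i=st.floats(0.1, 5.0), k=st.floats(0.01, 0.2), c0=st.floats(0.0, 100.0)
    )
    @settings(max_examples=50, deadline=None)
    def test_sign_matches_position_relative_to_steady_state(self, i, k, c0):
        # soils below I/k sequester, soils above lose C
        rate = transition_rate(i, k, c0)
        if c0 < i / k:
            assert rate > 0
        elif c0 > i / k:
            assert rate < 0

    def test_consistent_with_time_to_steady_state(self):
        # rate == (C* - C0) / years, algebraically
        rate = 0.31
        years = time_to_steady_state(55.0, 43.0, rate)
        assert (55.0 - 43.0) / years == pytest.approx(rate)


class TestAreaWeighting:
    def test_nsi_site_counts_give_0_18(self):
        rate = area_weighted_rate(0.28, AreaWeights(552, 301))
        assert rate == pytest.approx(0.18, abs=0.005)

    def test_no_grass_sites_leaves_rate_unchanged(self):
        assert area_weighted_rate(0.28, AreaWeights(552, 0)) == pytest.approx(0.28)

    def test_equal_counts_halve_the_rate(self):
        assert area_weighted_rate(0.5, AreaWeights(1, 1)) == pytest.approx(0.25)


class TestTimeToSteadyState:
    def test_worked_example_42_years(self):
        assert time_to_steady_state(55.02, 43.15, 0.28, round_to=0) == 42

    @pytest.mark.parametrize("c_star, c0, rate, expected", [(50, 40, 0.5, 20), (50, 50, 0.5, 0)])
    def test_hand_arithmetic(self, c_star, c0, rate, expected):
        assert time_to_steady_state(c_star, c0, rate) == pytest.approx(expected)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            time_to_steady_state(50, 40, 0.0)


class TestCToCo2:
    @pytest.mark.parametrize(
        "c, co2, tol",
        [(0.28, 1.03, 0.005), (0.18, 0.66, 0.005), (12.0, 44.0, 1e-9), (I_RG, 9.3, 0.05)],
    )
    def test_molar_conversion(self, c, co2, tol):
        assert c_to_co2(c) == pytest.approx(co2, abs=tol)

    @given(st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_linear_and_self_inverse(self, x):
        assert c_to_co2(x) * 12.0 / 44.0 == pytest.approx(x, abs=1e-9)


class TestFit:
    def test_exact_interpolation_of_two_rate_points(self):
        pts = [(c, I_RG - K_RG * c) for c in (30.0, 60.0)]
        i, k = fit_single_pool(pts)
        assert i == pytest.approx(I_RG, rel=1e-9)
        assert k == pytest.approx(K_RG, rel=1e-9)

    def test_recovers_parameters_from_noisy_sites(self):
        rng = np.random.default_rng(42)
        true_i, true_k = 2.5, 0.05
        c = rng.uniform(20, 80, size=200)
        dcdt = true_i - true_k * c + rng.normal(0, 0.1, size=200)
        i, k = fit_single_pool(list(zip(c, dcdt)))
        assert i == pytest.approx(true_i, rel=0.05)
        assert k == pytest.approx(true_k, rel=0.05)

    def test_steady_state_class_has_near_zero_rate_at_mean(self):
        # permanent pasture at steady state: fitted I - k*mean(C) ~ 0
        rng = np.random.default_rng(3)
        true_i, true_k = 2.0, 0.04  # steady state 50
        c = rng.uniform(45, 55, size=300)
        dcdt = true_i - true_k * c + rng.normal(0, 0.05, size=300)
        i, k = fit_single_pool(list(zip(c, dcdt)))
        assert i - k * c.mean() == pytest.approx(0.0, abs=0.05)

    def test_series_mode_recovers_noise_free_trajectory(self):
        p = SoilCarbonParams(I_RG, K_RG, C_ARABLE)
        ts = np.linspace(0, 40, 20)
        i, k = fit_single_pool(list(zip(ts, trajectory(p, ts))), mode="series")
        assert i == pytest.approx(I_RG, rel=1e-6)
        assert k == pytest.approx(K_RG, rel=1e-6)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_single_pool([(50.0, 0.1), (50.0, 0.2)])
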