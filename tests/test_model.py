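"""Unit and property tests for the association-kinetics models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import solve_ivp

import hetflow as hf
from hetflow.model import HOUR_TO_S

TIMES = np.array(hf.presets.STANDARD_TIMES)


def ode_homogeneous(t_h, r, K, consts, rtol=1e-11):
    """Independent oracle: numerically integrate the media-depletion ODE."""

    def rhs(t, y):
        P = consts.V * (consts.u0 - y[0])
        return [-consts.C * consts.S * r / consts.V * (K - P) / K * y[0]]

    t_h = np.atleast_1d(np.asarray(t_h, dtype=float))
    sol = solve_ivp(
        rhs, (0.0, t_h.max() * HOUR_TO_S), [consts.u0],
        t_eval=t_h * HOUR_TO_S, rtol=rtol, atol=consts.u0 * 1e-14,
    )
    return consts.V * (consts.u0 - sol.y[0])


class TestHomogeneousSolution:
    def test_initial_condition_and_zero_rate(self, consts):
        assert hf.homogeneous_solution(0.0, 1e-7, 10.0, consts) == 0.0
        assert hf.homogeneous_solution(24.0, 0.0, 10.0, consts) == 0.0

    def test_long_time_limit_is_capacity(self, consts):
        # K < Vu0: P approaches the carrying capacity
        p = hf.homogeneous_solution(1e7, 3.86e-7, 10.0, consts)
        assert p == pytest.approx(10.0, rel=1e-9)

    def test_matches_ode_oracle_on_fixture(self, consts):
        p_an = hf.homogeneous_solution(TIMES, 3.86e-7, 10.0, consts)
        p_ode = ode_homogeneous(TIMES, 3.86e-7, 10.0, consts)
        assert np.max(np.abs(p_an - p_ode) / p_ode) < 1e-6

    def test_matches_ode_oracle_random_parameters(self, consts, rng):
        for _ in range(20):
            r = 10 ** rng.uniform(-8.5, -6.0)
            K = 10 ** rng.uniform(0.0, 2.7)
            p_an = hf.homogeneous_solution(TIMES, r, K, consts)
            p_ode = ode_homogeneous(TIMES, r, K, consts)
            assert np.max(np.abs(p_an - p_ode) / np.maximum(p_ode, 1e-12)) < 1e-6

    def test_continuous_across_branch_switch(self, consts):
        vu0 = consts.vu0
        p_eq = hf.homogeneous_solution(TIMES, 1e-7, vu0, consts)
        for K in (vu0 * (1 - 1e-7), vu0 * (1 + 1e-7)):
            p = hf.homogeneous_solution(TIMES, 1e-7, K, consts)
            assert np.allclose(p, p_eq, rtol=1e-5)

    def test_equal_branch_matches_ode(self, consts):
        K = consts.vu0
        p_an = hf.homogeneous_solution(TIMES, 5e-8, K, consts)
        p_ode = ode_homogeneous(TIMES, 5e-8, K, consts)
        assert np.max(np.abs(p_an - p_ode) / p_ode) < 1e-6

    def test_rejects_bad_parameters(self, consts):
        with pytest.raises(ValueError):
            hf.homogeneous_solution(-1.0, 1e-7, 10.0, consts)
        with pytest.raises(ValueError):
            hf.homogeneous_solution(1.0, 1e-7, -10.0, consts)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        logr=st.floats(-9, -5.5),
        logK=st.floats(0, 3),
        t=st.floats(0, 48),
    )
    def test_bounds_property(self, logr, logK, t):
        consts = hf.presets.DEFAULT_CONSTANTS
        p = hf.homogeneous_solution(t, 10**logr, 10**logK, consts)
        assert 0.0 <= p <= min(10**logK, consts.vu0) * (1 + 1e-12)


class TestLognormalParams:
    def test_degenerate_limit(self):
        mu, sigma = hf.lognormal_natural_params(1.0, 1e-12)
        assert abs(mu) < 1e-15 and sigma < 1e-11

    def test_monte_carlo_matches_closed_form(self, rng):
        mu, sigma = hf.lognormal_natural_params(51.2, 53.3)
        draws = rng.lognormal(mu, sigma, 10**6)
        assert draws.mean() == pytest.approx(51.2, rel=0.01)
        assert draws.std() == pytest.approx(53.3, rel=0.02)

    def test_scale_property(self):
        mu1, s1 = hf.lognormal_natural_params(51.2, 53.3)
        mu2, s2 = hf.lognormal_natural_params(3 * 51.2, 3 * 53.3)
        assert mu2 - mu1 == pytest.approx(np.log(3), abs=1e-12)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            hf.lognormal_natural_params(0.0, 1.0)
        with pytest.raises(ValueError):
            hf.lognormal_natural_params(1.0, -1.0)


class TestCellTraits:
    def test_mean_within_clt_bound(self, rng):
        hyper = hf.presets.RECOVERY_HYPERPARAMS
        n = 20_000
        traits = hf.sample_cell_traits(hyper, n, rng)
        se = hyper.s_K / np.sqrt(n)
        assert abs(traits.K.mean() - hyper.m_K) < 3 * se

    def test_degenerate_spread_gives_identical_cells(self, rng):
        hyper = hf.HyperParams(1e-7, 1e-15, 10.0, 1e-8)
        traits = hf.sample_cell_traits(hyper, 100, rng)
        assert np.ptp(traits.r) / traits.r.mean() < 1e-6
        assert np.ptp(traits.K) / traits.K.mean() < 1e-6

    def test_deterministic_given_seed(self):
        hyper = hf.presets.RECOVERY_HYPERPARAMS
        a = hf.sample_cell_traits(hyper, 1000, np.random.default_rng(3))
        b = hf.sample_cell_traits(hyper, 1000, np.random.default_rng(3))
        assert np.array_equal(a.r, b.r) and np.array_equal(a.K, b.K)

    def test_log_traits_are_gaussian(self):
        hyper = hf.presets.RECOVERY_HYPERPARAMS
        traits = hf.sample_cell_traits(hyper, 10**5, np.random.default_rng(12))
        mu, sigma = hf.lognormal_natural_params(hyper.m_r, hyper.s_r)
        assert stats.kstest(np.log(traits.r), "norm", args=(mu, sigma)).pvalue > 0.01
        mu, sigma = hf.lognormal_natural_params(hyper.m_K, hyper.s_K)
        assert stats.kstest(np.log(traits.K), "norm", args=(mu, sigma)).pvalue > 0.01


class TestMediaConcentration:
    def test_initial_value_and_monotonicity(self, consts, rng):
        media = hf.media_concentration_approx(TIMES, hf.presets.RECOVERY_HYPERPARAMS, consts, 100, rng)
        assert media.ubar[0] == pytest.approx(consts.u0)
        assert np.all(np.diff(media.ubar) <= 1e-12 * consts.u0)
        assert np.all(np.diff(media.cumint) >= 0)
        assert media.cumint[0] == 0.0

    def test_degenerate_population_equals_homogeneous(self, consts, rng):
        hyper = hf.HyperParams(3.86e-7, 3.86e-15, 10.0, 1e-8)
        media = hf.media_concentration_approx(TIMES, hyper, consts, 50, rng)
        u_hom = consts.u0 - hf.homogeneous_solution(media.times, hyper.m_r, hyper.m_K, consts) / consts.V
        assert np.allclose(media.ubar, u_hom, rtol=1e-6)

    def test_lower_bound_from_capacity(self, consts, rng):
        hyper = hf.presets.RECOVERY_HYPERPARAMS
        media = hf.media_concentration_approx(TIMES, hyper, consts, 200, rng)
        floor = consts.u0 - (hyper.m_K + 5 * hyper.s_K) / consts.V
        assert np.all(media.ubar >= floor)

    def test_empty_grid_rejected(self, consts, rng):
        with pytest.raises(ValueError):
            hf.media_concentration_approx([], hf.presets.RECOVERY_HYPERPARAMS, consts, 10, rng)


class TestHeterogeneousApprox:
    def test_degenerate_reduces_to_homogeneous(self, consts, rng):
        # spread -> 0: every cell follows the analytic homogeneous solution
        hyper = hf.HyperParams(3.86e-7, 3.86e-16, 10.0, 1e-9)
        traits = hf.sample_cell_traits(hyper, 20, rng)
        media = hf.media_concentration_approx(TIMES, hyper, consts, 50, rng)
        traj = hf.heterogeneous_solution_approx(TIMES, traits, media, consts)
        p_hom = hf.homogeneous_solution(TIMES, hyper.m_r, hyper.m_K, consts)
        assert np.max(np.abs(traj.P - p_hom[None, :]) / p_hom[None, :]) < 1e-6

    def test_trajectories_bounded_and_start_at_zero(self, consts, rng):
        hyper = hf.presets.RECOVERY_HYPERPARAMS
        traits = hf.sample_cell_traits(hyper, 500, rng)
        t = np.concatenate([[0.0], TIMES])
        media = hf.media_concentration_approx(t, hyper, consts, 100, rng)
        traj = hf.heterogeneous_solution_approx(t, traits, media, consts)
        assert np.all(traj.P[:, 0] == 0.0)
        # strictly below capacity mathematically; equality only at the
        # float-precision saturation limit
        assert np.all(traj.P <= traits.K[:, None])
        assert np.all(traj.P[:, 0] < traits.K)
        assert np.all(traj.P >= 0)
        assert np.all(np.diff(traj.P, axis=1) >= 0)
        assert np.all(traj.P <= consts.vu0)

    def test_time_outside_media_grid_rejected(self, consts, rng):
        hyper = hf.presets.RECOVERY_HYPERPARAMS
        traits = hf.sample_cell_traits(hyper, 5, rng)
        media = hf.media_concentration_approx([1.0], hyper, consts, 10, rng)
        with pytest.raises(ValueError):
            hf.heterogeneous_solution_approx([2.0], traits, media, consts)


class TestHeterogeneousFull:
    def test_identical_cells_match_homogeneous(self, consts):
        traits = hf.CellTraits(np.full(5, 3.86e-7), np.full(5, 10.0))
        traj = hf.heterogeneous_solution_full(TIMES, traits, consts)
        p_hom = hf.homogeneous_solution(TIMES, 3.86e-7, 10.0, consts)
        assert np.allclose(traj.P, p_hom[None, :], rtol=1e-6)

    def test_particle_conservation(self, consts, rng):
        hyper = hf.presets.SCENARIO_HYPERPARAMS["intermediate"]
        traits = hf.sample_cell_traits(hyper, 50, rng)
        traj = hf.heterogeneous_solution_full(TIMES, traits, consts)
        n = len(traits)
        total = n * consts.V * traj.u + traj.P.sum(axis=0)
        assert np.allclose(total, n * consts.vu0, rtol=1e-7)

    def test_faster_cells_deplete_media_more(self, consts, rng):
        hyper = hf.presets.SCENARIO_HYPERPARAMS["intermediate"]
        traits = hf.sample_cell_traits(hyper, 30, rng)
        fast = hf.CellTraits(2 * traits.r, traits.K.copy())
        u_slow = hf.heterogeneous_solution_full(TIMES, traits, consts).u
        u_fast = hf.heterogeneous_solution_full(TIMES, fast, consts).u
        assert np.all(u_fast <= u_slow * (1 + 1e-12))

    def test_approx_error_vanishes_with_dose(self, rng):
        # raising u0 (with Vu0 growing) shrinks depletion, so the mean-field
        # approximation error at 24 h decreases monotonically
        hyper = hf.presets.SCENARIO_HYPERPARAMS["intermediate"]
        traits = hf.sample_cell_traits(hyper, 100, np.random.default_rng(5))
        errs = []
        for u0 in (1e11, 1e12, 1e13):
            consts = hf.ExperimentConstants(C=0.3, S=5.5e-10, V=1.0e-9, u0=u0)
            media = hf.media_concentration_approx(TIMES, hyper, consts, 100, np.random.default_rng(8))
            approx = hf.heterogeneous_solution_approx(TIMES, traits, media, consts)
            full = hf.heterogeneous_solution_full(TIMES, traits, consts)
            errs.append(np.max(np.abs(approx.P[:, -1] - full.P[:, -1]) / full.P[:, -1]))
        assert errs[0] > errs[1] > errs[2]
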