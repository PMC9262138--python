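"""Unit and property tests for the circuit model and its solvers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autosplice import model_core as mc
from conftest import random_params


class TestHillRepression:
    @pytest.mark.parametrize("p_eff,k,h,expected", [
        (0.0, 5.0, 2.0, 1.0),        # zero-protein limit
        (5.0, 5.0, 2.0, 0.5),        # half-maximum by definition
        (3.0, 3.0, 1.7, 0.5),
        (2.0, 1.0, 2.0, 0.2),        # 1/(1+4)
    ])
    def test_values(self, p_eff, k, h, expected):
        assert mc.hill_repression(p_eff, k, h) == pytest.approx(expected)

    def test_monotone_decreasing_and_limits(self):
        grid = np.linspace(0.0, 100.0, 200)
        vals = mc.hill_repression(grid, 5.0, 2.5)
        assert np.all(np.diff(vals) < 0)
        assert vals[0] == 1.0
        assert mc.hill_repression(1e9, 5.0, 2.5) < 1e-10

    @pytest.mark.parametrize("k,h", [(0.0, 2.0), (-1.0, 2.0), (5.0, 0.0)])
    def test_domain_errors(self, k, h):
        with pytest.raises(mc.ParameterError):
            mc.hill_repression(1.0, k, h)


class TestEffectiveProtein:
    @pytest.mark.parametrize("u_s,u_o,R,p,expected", [
        (1.0, 0.0, 0.0, 7.0, 7.0),      # sole substrate takes all protein
        (1.0, 0.0, 299.0, 300.0, 1.0),  # 1/300 share of 300
        (1.0, 1.0, 2.0, 8.0, 2.0),      # quarter share
    ])
    def test_allocation(self, u_s, u_o, R, p, expected):
        assert mc.effective_protein(u_s, u_o, R, p) == pytest.approx(expected)

    def test_zero_substrate_is_an_error(self):
        with pytest.raises(mc.AllocationError):
            mc.effective_protein(0.0, 0.0, 0.0, 5.0)

    def test_decreasing_in_reservoir(self):
        vals = [mc.effective_protein(1.0, 1.0, r, 10.0) for r in (0, 1, 10, 100)]
        assert np.all(np.diff(vals) < 0)


class TestRhs:
    def test_no_feedback_empty_system(self, default_params):
        d = mc.rhs_no_feedback(mc.CircuitState(), default_params, 0.0)
        assert d.m_ec == 0.0 and d.p_ec == 0.0

    def test_no_feedback_steady_state_annihilates(self, default_params):
        p = default_params
        a = 3.0
        st_ = mc.CircuitState(m_ec=a / p.beta_m,
                              p_ec=p.gamma * a / (p.beta_m * p.beta_p))
        d = mc.rhs_no_feedback(st_, p, a)
        assert d.m_ec == pytest.approx(0.0, abs=1e-12)
        assert d.p_ec == pytest.approx(0.0, abs=1e-12)

    def test_no_feedback_direct_substitution(self, default_params):
        p = default_params.replace(beta_m=1.0, gamma=2.0, beta_p=0.1)
        d = mc.rhs_no_feedback(mc.CircuitState(m_ec=1.0, p_ec=0.0), p, 0.0)
        assert d.m_ec == pytest.approx(-1.0)
        assert d.p_ec == pytest.approx(2.0)

    def test_feedback_zero_state_zero_production(self, default_params):
        p = default_params.replace(alpha_en=0.0)
        d = mc.rhs_feedback(mc.CircuitState(), p, 0.0)
        assert np.allclose(d.to_array(), 0.0)

    def test_feedback_kappa_zero_mrna_pure_decay(self, default_params):
        p = default_params.replace(kappa=0.0)
        s = mc.CircuitState(u_ec=3.0, m_ec=2.0, u_en=1.0, m_en=4.0)
        d = mc.rhs_feedback(s, p, 0.0)
        assert d.m_ec == pytest.approx(-p.beta_m * 2.0)
        assert d.m_en == pytest.approx(-p.beta_m * 4.0)

    def test_feedback_large_reservoir_limit(self, default_params):
        p = default_params.replace(reservoir=1e12)
        s = mc.CircuitState(u_ec=3.0, m_ec=2.0, p_ec=50.0,
                            u_en=1.0, m_en=4.0, p_en=100.0)
        d = mc.rhs_feedback(s, p, 0.0)
        assert d.m_ec == pytest.approx(p.kappa * 3.0 - p.beta_m * 2.0, rel=1e-9)
        assert d.m_en == pytest.approx(p.kappa * 1.0 - p.beta_m * 4.0, rel=1e-9)


class TestAnalyticNoFeedback:
    def test_initial_and_asymptotic_values(self, default_params):
        p = default_params
        m0, p0 = mc.analytic_no_feedback(p, 5.0, 0.0)
        assert m0 == 0.0 and p0 == 0.0
        m_inf, p_inf = mc.analytic_no_feedback(p, 5.0, 1e4)
        assert m_inf == pytest.approx(5.0 / p.beta_m, rel=1e-9)
        assert p_inf == pytest.approx(p.gamma * 5.0 / (p.beta_m * p.beta_p),
                                      rel=1e-9)

    def test_confluent_branch(self, default_params):
        # beta_m == beta_p == gamma == alpha == 1: p(t) = 1 - (1+t) e^-t
        p = default_params.replace(beta_m=1.0, beta_p=1.0, gamma=1.0)
        _, pv = mc.analytic_no_feedback(p, 1.0, 1.0)
        assert pv == pytest.approx(1.0 - 2.0 * np.exp(-1.0), rel=1e-9)

    def test_confluent_matches_nearby_distinct_rates(self, default_params):
        p1 = default_params.replace(beta_m=1.0, beta_p=1.0 + 1e-10)
        p2 = default_params.replace(beta_m=1.0, beta_p=1.0)
        t = np.linspace(0, 20, 50)
        _, a = mc.analytic_no_feedback(p1, 2.0, t)
        _, b = mc.analytic_no_feedback(p2, 2.0, t)
        assert np.allclose(a, b, rtol=1e-6)


class TestSimulate:
    def test_zero_production_stays_at_background(self, default_params):
        p = default_params.replace(alpha_ec_hi=0.0)
        traj = mc.simulate(p, "no_feedback", "high")
        assert np.all(traj.observable == p.bg)

    def test_matches_analytic_solution(self, default_params):
        t = mc.default_times()
        traj = mc.simulate(default_params, "no_feedback", "low", t)
        _, pa = mc.analytic_no_feedback(default_params,
                                        default_params.alpha_ec_lo, t,
                                        t_delay=default_params.t_delay_lo)
        mask = pa > default_params.bg
        rel = np.abs(traj.states[mask, 2] - pa[mask]) / pa[mask]
        assert rel.max() < 1e-6

    def test_long_horizon_reaches_feedback_fixed_point(self, default_params):
        ss = mc.steady_state_feedback(default_params,
                                      default_params.alpha_ec_hi)
        traj = mc.simulate(default_params, "feedback", "high",
                           np.array([0.0, 2000.0]))
        final = traj.states[-1]
        expect = ss.to_array()
        rel = np.abs(final - expect) / np.maximum(np.abs(expect), 1e-12)
        assert rel.max() < 1e-6

    def test_delay_gates_production(self, default_params):
        traj = mc.simulate(default_params, "no_feedback", "low")
        before = traj.times < default_params.t_delay_lo
        assert np.all(traj.observable[before] == default_params.bg)

    def test_observable_floor_invariant(self, default_params):
        for circ in ("no_feedback", "feedback"):
            traj = mc.simulate(default_params, circ, "high")
            assert np.all(traj.observable >= default_params.bg)

    def test_nonnegative_species_random_params(self, rng):
        for _ in range(10):
            p = random_params(rng, active=False)
            traj = mc.simulate(p, "feedback", "high")
            assert traj.states.min() >= 0.0

    def test_fast_path_agrees_with_adaptive(self, rng):
        t = mc.default_times()
        for _ in range(5):
            p = random_params(rng, active=False)
            a = mc.simulate(p, "feedback", "low", t)
            b = mc.simulate_fast(p, "feedback", "low", t)
            scale = np.maximum(np.abs(a.states).max(axis=0), 1e-9)
            assert np.max(np.abs(a.states - b.states) / scale) < 1e-5

    def test_invalid_time_grid(self, default_params):
        with pytest.raises(ValueError):
            mc.simulate(default_params, "feedback", "high",
                        np.array([1.0, 0.5]))


class TestSteadyStateFeedback:
    def test_kappa_zero(self, default_params):
        p = default_params.replace(kappa=0.0)
        ss = mc.steady_state_feedback(p, 7.0)
        assert ss.m_ec == 0.0 and ss.p_ec == 0.0
        assert ss.u_ec == pytest.approx(7.0 / p.beta_u)
        assert ss.u_en == pytest.approx(p.alpha_en / p.beta_u)

    def test_large_reservoir_limit(self, default_params):
        p = default_params.replace(reservoir=1e12)
        ss = mc.steady_state_feedback(p, 7.0)
        expect = p.gamma * p.kappa * 7.0 / (p.beta_u * p.beta_m * p.beta_p)
        assert ss.p_ec == pytest.approx(expect, rel=1e-8)

    def test_residual_norm_random_params(self, rng):
        for _ in range(10):
            p = random_params(rng)
            ss = mc.steady_state_feedback(p, p.alpha_ec_hi)
            resid = mc.rhs_feedback(ss, p, p.alpha_ec_hi).to_array()
            assert np.linalg.norm(resid) < 1e-9 * max(
                1.0, np.abs(ss.to_array()).max())


class TestParameters:
    def test_roundtrip_dict(self, default_params):
        d = default_params.to_dict()
        assert mc.ModelParameters.from_dict(d) == default_params

    def test_unknown_key_rejected(self):
        with pytest.raises(mc.ParameterError):
            mc.ModelParameters.from_dict({"alpha_ec_lo": 1.0, "bogus": 2.0})

    @pytest.mark.parametrize("field,value", [
        ("beta_m", 0.0), ("beta_p", -1.0), ("k_half", 0.0),
        ("h_hill", -2.0), ("alpha_en", -1.0), ("sigma_obs", -0.1),
    ])
    def test_domain_validation(self, field, value):
        with pytest.raises(mc.ParameterError):
            mc.ModelParameters(**{field: value})

    def test_equilibrated_initial_conditions_are_stationary(self, default_params):
        p = default_params.equilibrated()
        traj = mc.simulate(p, "feedback", "low", np.linspace(0, 5, 10))
        pre = traj.times < p.t_delay_lo
        drift = np.abs(traj.states[pre, 5] - p.p0_en) / p.p0_en
        assert drift.max() < 1e-6


@settings(max_examples=25, deadline=None, derandomize=True)
@given(p_eff=st.floats(0.0, 1e6), k=st.floats(1e-3, 1e3),
       h=st.floats(0.5, 6.0))
def test_hill_always_in_unit_interval(p_eff, k, h):
    v = mc.hill_repression(p_eff, k, h)
    assert 0.0 <= v <= 1.0


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_steady_state_matches_long_integration(seed):
    """Root-finding fixed point equals the 2000 h integration endpoint."""
    p = random_params(np.random.default_rng(seed))
    ss = mc.steady_state_feedback(p, p.alpha_ec_hi)
    traj = mc.simulate(p, "feedback", "high", np.array([0.0, 2000.0]))
    expect = ss.to_array()
    rel = np.abs(traj.states[-1] - expect) / np.maximum(np.abs(expect), 1e-12)
    assert rel.max() < 1e-6
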