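"""Tests for the Bayesian fitting machinery (likelihood, screen, sampler)."""

import math

import numpy as np
import pytest

from autosplice import inference as inf
from autosplice import synthetic_data as sd
from autosplice.model_core import Circuit, Induction, ModelParameters


@pytest.fixture(scope="module")
def truth() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="module")
def noiseless(truth):
    data, _ = sd.generate_average_curves(truth.replace(sigma_obs=0.0), seed=5)
    return data


@pytest.fixture(scope="module")
def data(truth):
    d, _ = sd.generate_average_curves(truth, seed=5)
    return d


class TestLogLikelihood:
    def test_zero_residuals_normalization(self, truth, noiseless):
        """With a perfect fit and sigma=1 only the Gaussian norm remains."""
        p = truth.replace(sigma_obs=1.0)
        n = sum(len(v) for v in noiseless.curves.values())
        ll = inf.log_likelihood(p, noiseless)
        assert ll == pytest.approx(-(n / 2) * math.log(2 * math.pi), rel=1e-9)

    def test_doubling_sigma_costs_n_log_two(self, truth, noiseless):
        n = sum(len(v) for v in noiseless.curves.values())
        l1 = inf.log_likelihood(truth.replace(sigma_obs=1.0), noiseless)
        l2 = inf.log_likelihood(truth.replace(sigma_obs=2.0), noiseless)
        assert l1 - l2 == pytest.approx(n * math.log(2.0), rel=1e-9)

    def test_hand_computed_toy_grid(self, truth):
        """Three-point toy curve against explicit Gaussian arithmetic."""
        times = np.array([30.0, 35.0, 40.0])
        key = (Circuit.NO_FEEDBACK, Induction.HIGH)
        from autosplice.model_core import simulate_fast

        pred = simulate_fast(truth, *key, times).observable
        obs = pred + np.array([1.0, -2.0, 0.5])
        data = sd.CurveSet(times=times, curves={key: obs})
        sigma = truth.sigma_obs
        expect = sum(-0.5 * (r / sigma) ** 2 - math.log(sigma)
                     - 0.5 * math.log(2 * math.pi) for r in (1.0, -2.0, 0.5))
        assert inf.log_likelihood(truth, data) == pytest.approx(expect, rel=1e-6)

    def test_nonpositive_sigma_rejected(self, truth, noiseless):
        assert inf.log_likelihood(truth.replace(sigma_obs=0.0), noiseless) == -np.inf


class TestPriors:
    def test_prior_medians_and_logpdf_finite(self):
        for name, prior in inf.default_priors().items():
            m = prior.median()
            assert m > 0
            assert np.isfinite(prior.logpdf(m))
            assert prior.logpdf(-1.0) == -np.inf

    def test_lognormal_prior_mass_spans_four_decades(self):
        pr = inf.default_priors()["beta_m"]
        lo = 0.3 * 10 ** (-2)
        hi = 0.3 * 10 ** 2
        from scipy import stats

        mass = (stats.norm.cdf(math.log(hi), pr.a, pr.b)
                - stats.norm.cdf(math.log(lo), pr.a, pr.b))
        assert mass == pytest.approx(0.95, abs=0.01)

    def test_posterior_factorizes(self, truth, data):
        """log posterior equals log prior plus log likelihood, spot checks."""
        spec = inf.FitSpec(seed=0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            theta = np.log([spec.priors[n].median() for n in spec.param_names])
            theta = theta + 0.3 * rng.standard_normal(len(theta))
            lp = inf.log_prior(theta, spec)
            params = spec.make_params(np.exp(theta), (8.25, 0.25))
            ll = inf.log_likelihood(params, data, substeps=spec.substeps)
            assert inf.log_posterior(theta, spec, data, (8.25, 0.25)) == \
                pytest.approx(lp + ll, rel=1e-12)


class TestFitSpec:
    def test_default_delay_grid_has_65_pairs(self):
        spec = inf.FitSpec()
        pairs = spec.delay_grid()
        assert len(pairs) == 65
        lows = sorted({p[0] for p in pairs})
        highs = sorted({p[1] for p in pairs})
        assert lows[0] == 6.0 and lows[-1] == 9.0 and len(lows) == 13
        assert highs[0] == 0.0 and highs[-1] == 1.0 and len(highs) == 5

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            inf.FitSpec(warmup=2000, iterations=2000)
        with pytest.raises(ValueError):
            inf.FitSpec(delay_grid_lo=(9.0, 6.0, 0.25))
        with pytest.raises(ValueError):
            inf.FitSpec(priors={})

    def test_make_params_applies_updates_and_delays(self, truth):
        spec = inf.FitSpec(base=truth)
        theta = [spec.priors[n].median() for n in spec.param_names]
        p = spec.make_params(np.array(theta), (7.0, 0.5))
        assert p.t_delay_lo == 7.0 and p.t_delay_hi == 0.5
        assert p.gamma == truth.gamma  # fixed parameter untouched


class TestSampler:
    def test_prior_only_sampling_recovers_prior_quantiles(self):
        """With no data the sampler must reproduce the prior distribution."""
        priors = {"beta_m": inf.default_priors()["beta_m"],
                  "kappa": inf.default_priors()["kappa"]}
        spec = inf.FitSpec(priors=priors, iterations=2500, warmup=500, seed=3)
        empty = sd.CurveSet(times=np.array([0.0, 1.0]), curves={})
        sample = inf.sample_posterior(empty, spec, (0.0, 0.0),
                                      init=np.log([0.3, 1.0]))
        for i, name in enumerate(sample.param_names):
            draws = np.log(sample.flat()[:, i])
            pr = priors[name]
            assert np.median(draws) == pytest.approx(pr.a, abs=0.15 * pr.b)
            assert np.std(draws) == pytest.approx(pr.b, rel=0.15)

    def test_seed_determinism(self, data):
        spec = inf.FitSpec(iterations=40, warmup=10, seed=9)
        a = inf.sample_posterior(data, spec, (8.25, 0.25))
        b = inf.sample_posterior(data, spec, (8.25, 0.25))
        assert np.array_equal(a.draws, b.draws)

    def test_summaries_recomputable_from_draws(self, data):
        spec = inf.FitSpec(iterations=60, warmup=20, seed=2)
        s = inf.sample_posterior(data, spec, (8.25, 0.25))
        flat = s.flat()
        for i, n in enumerate(s.param_names):
            assert s.medians[n] == pytest.approx(float(np.median(flat[:, i])))
            assert s.ci_lower[n] <= s.medians[n] <= s.ci_upper[n]

    def test_draws_respect_nonnegativity(self, data):
        spec = inf.FitSpec(iterations=40, warmup=10, seed=4)
        s = inf.sample_posterior(data, spec, (8.25, 0.25))
        assert (s.flat() > 0).all()


class TestDelayScreen:
    def test_noiseless_screen_on_reduced_grid_finds_truth(self, truth, noiseless):
        """On noiseless data the SSE minimum sits at the true delay pair."""
        spec = inf.FitSpec(seed=1,
                           delay_grid_lo=(8.0, 8.5, 0.25),
                           delay_grid_hi=(0.0, 0.5, 0.25))
        res = inf.delay_screen(noiseless, spec)
        assert res.best == (8.25, 0.25)
        assert len(res.table) == 9

    def test_zero_delay_recovered_when_grid_contains_zero(self, truth):
        p = truth.replace(t_delay_hi=0.0, sigma_obs=0.0)
        data, _ = sd.generate_average_curves(p, seed=11)
        spec = inf.FitSpec(base=truth, seed=2,
                           delay_grid_lo=(8.25, 8.25, 0.25),
                           delay_grid_hi=(0.0, 0.5, 0.25))
        res = inf.delay_screen(data, spec)
        assert res.best[1] == 0.0


class TestPosteriorSummary:
    def test_half_life_inversion(self, data):
        spec = inf.FitSpec(iterations=40, warmup=10, seed=5)
        s = inf.sample_posterior(data, spec, (8.25, 0.25))
        summ = inf.posterior_summary(s)
        i = list(s.param_names).index("beta_p")
        hl = np.log(2.0) / s.flat()[:, i]
        assert summ.loc["half_life_p_h", "median"] == pytest.approx(
            float(np.median(hl)))

    def test_35_minute_half_life_unit_conversion(self):
        # constant draws at ln2 / (35/60) per hour invert to 35 minutes
        draws = np.full((2, 10, 1), math.log(2.0) / (35.0 / 60.0))
        s = inf.PosteriorSample(
            draws=draws, param_names=("beta_u",), delays=(8.25, 0.25),
            medians={"beta_u": float(draws[0, 0, 0])},
            ci_lower={"beta_u": 0.0}, ci_upper={"beta_u": 2.0},
            rhat={"beta_u": 1.0}, ess={"beta_u": 20.0})
        summ = inf.posterior_summary(s)
        assert summ.loc["half_life_u_h", "median"] * 60 == pytest.approx(35.0)

    def test_productive_fraction_at_default_operating_point(self, truth, data):
        """The flux ratio kappa*H/beta_u at the native operating point sits
        near the committed-to-productive fraction of the default regime."""
        spec = inf.FitSpec(iterations=40, warmup=10, seed=6)
        s = inf.sample_posterior(data, spec, (8.25, 0.25))
        summ = inf.posterior_summary(s, base=truth)
        frac = summ.loc["productive_fraction", "median"]
        assert 0.0 < frac < 1.5
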