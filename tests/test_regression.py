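"""Power-law fitting: point oracle, Bayesian recovery, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.base import clone

from reefmass import (
    PowerLawParams,
    PriorSpec,
    SizeWeightRegressor,
    fit_loglog_oracle,
    fit_posterior,
    predict_weight,
    summarise_fit,
)
from reefmass.mcmc import mc_se
from reefmass.regression import (
    DegenerateDesignError,
    InsufficientDataError,
    _loglik_rows,
)


class TestPredictWeight:
    def test_unit_diameter_returns_a(self):
        assert predict_weight(PowerLawParams(7.0, 2.5, 1.0), 1.0) == pytest.approx(7.0)

    def test_small_exponent_limit(self):
        assert predict_weight(PowerLawParams(2.0, 1e-12, 1.0), 13.4) == pytest.approx(2.0)

    def test_worked_value(self):
        # 0.5 * 10^2.8 evaluated independently
        assert predict_weight(PowerLawParams(0.5, 2.8, 1.0), 10.0) == pytest.approx(
            315.479, abs=5e-4)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            predict_weight(PowerLawParams(1.0, 2.0, 1.0), 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 5.0), b=st.floats(0.5, 3.5),
           d=st.floats(1.0, 40.0), eps=st.floats(0.01, 1.0))
    def test_strictly_increasing_in_diameter_and_a(self, a, b, d, eps):
        p = PowerLawParams(a, b, 1.0)
        assert predict_weight(p, d + eps) > predict_weight(p, d)
        assert predict_weight(PowerLawParams(a + eps, b, 1.0), d) > predict_weight(p, d)


class TestLogLogOracle:
    def test_two_point_exact_solution(self):
        p = fit_loglog_oracle(x=np.array([1.0, 10.0]), y=np.array([4.0, 400.0]))
        assert p.a == pytest.approx(4.0)
        assert p.b == pytest.approx(2.0)

    def test_noiseless_data_recovered_exactly(self):
        d = np.array([2.0, 4.0, 8.0, 16.0])
        p = fit_loglog_oracle(x=d, y=2.0 * d**2.5)
        assert p.a == pytest.approx(2.0, rel=1e-10)
        assert p.b == pytest.approx(2.5, rel=1e-10)

    def test_estimates_within_ols_sampling_error(self, make_dataset):
        _, x, y, cfg = make_dataset(n=5000, seed=21, sigma_log=0.1)
        p = fit_loglog_oracle(x=x, y=y)
        lx = np.log(x)
        se_b = 0.1 / (np.sqrt(len(x)) * lx.std())
        assert abs(p.b - cfg.true_b) < 3 * se_b

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_loglog_oracle(x=np.array([5.0, 5.0, 5.0]), y=np.array([1.0, 2.0, 3.0]))


class TestLoglik:
    def test_matches_scipy_densities(self, make_dataset):
        """Pointwise log likelihood agrees with scipy's normal / lognormal."""
        _, x, y, _ = make_dataset(n=20, seed=2)
        theta = np.array([[0.3, 2.7, 25.0], [0.5, 2.5, 40.0]])
        mu = theta[:, :1] * x[None, :] ** theta[:, 1:2]
        ref = stats.norm.logpdf(y[None, :], mu, theta[:, 2:3])
        np.testing.assert_allclose(_loglik_rows("power", "gaussian", theta, x, y), ref)
        theta_ln = np.array([[0.3, 2.7, 0.2]])
        mu_ln = theta_ln[:, :1] * x[None, :] ** theta_ln[:, 1:2]
        ref_ln = stats.lognorm.logpdf(y[None, :], s=0.2, scale=mu_ln)
        np.testing.assert_allclose(
            _loglik_rows("power", "lognormal", theta_ln, x, y), ref_ln, rtol=1e-10)


class TestBayesianFit:
    def test_recovery_within_three_posterior_sd(self, make_dataset):
        _, x, y, cfg = make_dataset(n=300, seed=30)
        reg = SizeWeightRegressor(likelihood="lognormal", n_iter=4000,
                                  random_state=5).fit(x, y)
        for name, truth in (("a", cfg.true_a), ("b", cfg.true_b)):
            p = reg.summary_.params[name]
            assert abs(p["mean"] - truth) < 3 * p["se"]

    def test_small_noise_matches_oracle(self, make_dataset):
        _, x, y, _ = make_dataset(n=500, seed=31, sigma_log=0.02)
        ols = fit_loglog_oracle(x=x, y=y)
        reg = SizeWeightRegressor(likelihood="lognormal", n_iter=5000,
                                  random_state=6).fit(x, y)
        db = abs(np.mean(reg.draws_.flat("b")) - ols.b)
        assert db < 2 * mc_se(reg.draws_, "b")

    def test_prior_predictive_mode_returns_prior(self):
        draws = fit_posterior([], likelihood="lognormal",
                              priors=PriorSpec(sigma_scale=1.0),
                              n_iter=6000, seed=9)
        b = draws.flat("b")
        loga = np.log(draws.flat("a"))
        assert np.mean(b) == pytest.approx(3.0, abs=0.1)       # prior N(3,1), trunc >0
        assert np.std(b) == pytest.approx(1.0, rel=0.12)
        assert np.mean(loga) == pytest.approx(0.0, abs=0.2)    # prior N(0,2)
        assert np.std(loga) == pytest.approx(2.0, rel=0.12)

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            SizeWeightRegressor().fit(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_determinism(self, make_dataset):
        _, x, y, _ = make_dataset(n=50, seed=33)
        d1 = SizeWeightRegressor(n_iter=800, random_state=3).fit(x, y).draws_
        d2 = SizeWeightRegressor(n_iter=800, random_state=3).fit(x, y).draws_
        assert np.array_equal(d1.array, d2.array)

    def test_sklearn_protocol(self, make_dataset):
        reg = SizeWeightRegressor(likelihood="lognormal", n_iter=600, random_state=0)
        assert clone(reg).get_params() == reg.get_params()
        _, x, y, _ = make_dataset(n=40, seed=34)
        reg.fit(x.reshape(-1, 1), y)
        pred = reg.predict(np.array([[5.0], [10.0]]))
        assert pred.shape == (2,) and np.all(pred > 0)
        assert reg.score(x.reshape(-1, 1), y) > 0.5

    def test_emcee_cross_check(self, make_dataset):
        """Posterior mean of b agrees with an independent ensemble sampler
        run on the same log posterior."""
        emcee = pytest.importorskip("emcee")
        _, x, y, _ = make_dataset(n=150, seed=35)
        reg = SizeWeightRegressor(likelihood="lognormal", n_iter=5000,
                                  random_state=11).fit(x, y)

        from reefmass.regression import (PriorSpec, _default_priors, _log_prior,
                                         _loglik_rows, _natural)
        hyper = _default_priors("power", x, y, "lognormal", PriorSpec())

        def lp(theta):
            t = np.atleast_2d(theta)
            out = _log_prior("power", t, hyper)
            ok = np.isfinite(out)
            if ok.any():
                out[ok] += _loglik_rows("power", "lognormal",
                                        _natural("power", t[ok]), x, y).sum(axis=1)
            return out[0]

        p0 = np.array([np.log(0.3), 2.7, np.log(0.2)])
        rng = np.random.default_rng(12)
        sampler = emcee.EnsembleSampler(16, 3, lp)
        state = p0 + 0.01 * rng.standard_normal((16, 3))
        sampler.random_state = np.random.RandomState(12).get_state()
        sampler.run_mcmc(state, 1500)
        b_emcee = sampler.get_chain(discard=500, flat=True)[:, 1]
        b_mine = reg.draws_.flat("b")
        tol = 3 * np.sqrt(mc_se(reg.draws_, "b") ** 2 + np.var(b_emcee) / 500)
        assert abs(b_mine.mean() - b_emcee.mean()) < max(tol, 0.01)


class TestSummaries:
    def test_noiseless_r2_near_one(self, make_dataset):
        _, x, y, _ = make_dataset(n=100, seed=40, sigma_log=1e-6)
        reg = SizeWeightRegressor(likelihood="lognormal", n_iter=2000,
                                  random_state=8).fit(x, y)
        assert reg.summary_.bayes_r2 >= 0.999

    def test_no_signal_r2_near_zero(self, make_dataset):
        """Weights independent of diameter: explained variance collapses."""
        _, x, _, _ = make_dataset(n=1000, seed=41)
        rng = np.random.default_rng(41)
        y = 100.0 * np.exp(0.2 * rng.standard_normal(x.size))
        reg = SizeWeightRegressor(likelihood="lognormal", n_iter=3000,
                                  random_state=9).fit(x, y)
        assert reg.summary_.bayes_r2 <= 0.05

    def test_r2_matches_variance_decomposition(self, make_dataset):
        _, x, y, cfg = make_dataset(n=2000, seed=42)
        reg = SizeWeightRegressor(likelihood="lognormal", n_iter=3000,
                                  random_state=10).fit(x, y)
        var_mu = np.var(np.log(cfg.true_a) + cfg.true_b * np.log(x))
        expected = var_mu / (var_mu + cfg.sigma_log**2)
        assert reg.summary_.bayes_r2 == pytest.approx(expected, abs=0.05)

    def test_summary_reporting_fields(self, fitted_lognormal):
        reg, _ = fitted_lognormal
        s = reg.summary_
        for p in s.params.values():
            assert p["hdi_low"] < p["hdi_high"]
            assert p["se"] > 0
        assert 0.0 <= s.bayes_r2 <= 1.0
        assert s.n_obs == 300

    def test_empty_draws_rejected(self, fitted_lognormal):
        reg, _ = fitted_lognormal
        import dataclasses as dc
        empty = dc.replace(reg.draws_,
                           array=reg.draws_.array[:, :0, :])
        with pytest.raises(ValueError):
            summarise_fit(empty, x=reg.X_, y=reg.y_)
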