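import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from isilaw import (
    Beta2Params,
    MomentsUndefinedError,
    ValidationError,
    beta2_cv,
    beta2_mean,
    beta2_pdf,
    fit_beta2,
    fit_tail,
    GammaRateModel,
    LogBinnedHistogram,
    compute_isis,
    log_binned_histogram,
    simulate_constant_rate,
    simulate_superstat,
)
from tests.conftest import beta2_scipy

positive_shapes = st.floats(min_value=0.3, max_value=8.0)
scales = st.floats(min_value=5.0, max_value=500.0)


class TestPdf:
    def test_matches_scipy_betaprime(self, reference_params):
        t = np.geomspace(1.0, 1e4, 50)
        ours = beta2_pdf(t, reference_params)
        oracle = beta2_scipy(reference_params).pdf(t)
        assert np.allclose(ours, oracle, rtol=1e-12)

    def test_normalization_by_quadrature(self):
        params = Beta2Params(alpha=1.91, kappa=2.0, tau_ms=30.0)
        val, _ = integrate.quad(
            lambda t: beta2_pdf(t, params), 0, np.inf, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_small_t_limit_kappa_one(self):
        # alpha=kappa=1: p(T) = tau / (tau + T)^2 -> 1/tau at T -> 0+
        params = Beta2Params(alpha=1.0, kappa=1.0, tau_ms=100.0)
        assert beta2_pdf(1e-9, params) == pytest.approx(0.01, rel=1e-6)

    def test_mode_formula(self):
        params = Beta2Params(alpha=1.0, kappa=2.0, tau_ms=30.0)
        assert params.mode_ms == pytest.approx(15.0)
        t = np.linspace(1.0, 200.0, 20001)
        assert t[np.argmax(beta2_pdf(t, params))] == pytest.approx(15.0, abs=0.02)

    def test_rejects_nonpositive_t(self):
        with pytest.raises(ValidationError):
            beta2_pdf(np.array([-1.0]), Beta2Params(1.0, 1.0, 10.0))

    @given(alpha=positive_shapes, kappa=positive_shapes, tau=scales)
    @settings(max_examples=15, deadline=None)
    def test_normalization_property(self, alpha, kappa, tau):
        params = Beta2Params(alpha=alpha, kappa=kappa, tau_ms=tau)

        def integrand(u):
            t = np.exp(u)
            return beta2_pdf(t, params) * t

        # window wide enough for slow power tails at small shape values:
        # left mass ~ (T/tau)^kappa, right mass ~ (tau/T)^alpha
        lo = np.log(tau) - 60.0 / min(kappa, 1.0)
        hi = np.log(tau) + 60.0 / min(alpha, 1.0)
        val, _ = integrate.quad(integrand, lo, hi, limit=400)
        assert val == pytest.approx(1.0, abs=1e-7)

    def test_tail_slope_approaches_eta(self, reference_params):
        # local log-log slope converges to -(alpha+1); deviation at finite T
        # is ~ (alpha+kappa)*tau/T
        t = np.geomspace(1e7, 1e9, 10)
        slopes = np.gradient(np.log(beta2_pdf(t, reference_params)), np.log(t))
        assert np.allclose(slopes, -2.91, atol=1e-3)

    def test_small_t_slope_is_kappa_minus_one(self):
        params = Beta2Params(alpha=1.91, kappa=3.49, tau_ms=100.0)
        t = np.geomspace(1e-7, 1e-5, 10)
        slopes = np.gradient(np.log(beta2_pdf(t, params)), np.log(t))
        assert np.allclose(slopes, 2.49, atol=1e-3)


class TestMoments:
    def test_mean_formula(self):
        # alpha=2, kappa=1, R=10 spikes/s -> tau=200 ms, mean = 200 ms
        params = Beta2Params(alpha=2.0, kappa=1.0, tau_ms=200.0)
        assert params.rate_hz == pytest.approx(10.0)
        assert beta2_mean(params) == pytest.approx(200.0)

    def test_mean_diverges_near_one(self):
        params = Beta2Params(alpha=1.01, kappa=2.0, tau_ms=50.0)
        assert beta2_mean(params) == pytest.approx(100.0 * 50.0 * 2.0, rel=1e-9)

    def test_mean_matches_quadrature(self, reference_params):
        val, _ = integrate.quad(
            lambda t: t * beta2_pdf(t, reference_params), 0, np.inf, limit=500
        )
        assert beta2_mean(reference_params) == pytest.approx(val, rel=1e-6)

    def test_mean_requires_alpha_above_one(self):
        with pytest.raises(MomentsUndefinedError):
            beta2_mean(Beta2Params(alpha=1.0, kappa=2.0, tau_ms=50.0))

    def test_cv_matches_monte_carlo(self):
        # alpha well above 2 so the Monte-Carlo second moment converges
        params = Beta2Params(alpha=6.0, kappa=1.0, tau_ms=50.0)
        draws = beta2_scipy(params).rvs(size=1_000_000,
                                        random_state=np.random.default_rng(7))
        mc_cv = draws.std() / draws.mean()
        assert beta2_cv(params) == pytest.approx(mc_cv, rel=0.01)

    def test_cv_exponential_limit(self):
        # kappa=1, alpha -> inf: gamma(1) limit, CV -> 1
        assert beta2_cv(Beta2Params(alpha=1e4, kappa=1.0, tau_ms=1e4)) == (
            pytest.approx(1.0, abs=2e-4)
        )

    def test_cv_requires_alpha_above_two(self):
        with pytest.raises(MomentsUndefinedError):
            beta2_cv(Beta2Params(alpha=2.0, kappa=1.0, tau_ms=50.0))


class TestFit:
    def test_zero_noise_self_consistency(self, reference_params, exact_hist):
        fit = fit_beta2(exact_hist)
        assert fit.converged
        assert fit.params.alpha == pytest.approx(1.91, rel=1e-4)
        assert fit.params.kappa == pytest.approx(2.0, rel=1e-4)
        assert fit.params.tau_ms == pytest.approx(95.5, rel=1e-4)
        # reparameterization bookkeeping
        assert fit.c1 == pytest.approx(fit.params.kappa - 1.0)
        assert fit.c2 == pytest.approx(fit.params.alpha + fit.params.kappa)
        assert fit.c3 == pytest.approx(fit.params.tau_ms)

    def test_sampled_recovery(self):
        train = simulate_superstat(100_001, 2.0, GammaRateModel(1.91, 10.0), seed=11)
        hist = log_binned_histogram(compute_isis(train))
        fit = fit_beta2(hist)
        assert fit.params.alpha == pytest.approx(1.91, abs=0.15)
        assert fit.params.kappa == pytest.approx(2.0, abs=0.3)
        assert fit.params.rate_hz == pytest.approx(10.0, rel=0.1)
        # tail regression and fitted tail shape agree: eta ~ alpha+1
        eta = fit_tail(hist).eta
        assert abs(eta - (fit.params.alpha + 1.0)) < 0.45

    def test_constant_rate_data_flagged_unstable(self):
        # gamma interval data push alpha toward its bound (the compound law
        # only reaches the gamma law at alpha -> infinity)
        train = simulate_constant_rate(20_001, 3.0, 10.0, seed=12)
        hist = log_binned_histogram(compute_isis(train))
        fit = fit_beta2(hist)
        assert fit.unstable
        assert fit.params.alpha > 20.0

    def test_round_trip_across_seeds(self):
        # parameters -> per-interval simulation -> fit -> parameters
        errs = []
        for seed in range(8):
            train = simulate_superstat(
                20_001, 2.0, GammaRateModel(1.5, 10.0), seed=seed
            )
            fit = fit_beta2(log_binned_histogram(compute_isis(train)))
            errs.append(fit.params.alpha - 1.5)
        assert np.max(np.abs(errs)) < 0.3
        assert abs(np.mean(errs)) < 0.1

    def test_too_few_bins_rejected(self):
        from isilaw import ISISample

        hist = log_binned_histogram(ISISample(intervals_ms=np.full(60, 5.0)))
        with pytest.raises(ValidationError):
            fit_beta2(hist)
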