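"""Background model: truncated-normal fit, EM mixture deconvolution,
posterior-mean correction against an independent quadrature oracle."""

import numpy as np
import pytest
from scipy import integrate, stats

from beadprep.background import (
    BackgroundModel,
    SignalMixtureParams,
    TruncNormParams,
    correct_intensities,
    estimate_background,
    fit_signal_mixture,
)
from beadprep.baselines import NormexpParams, _normexp_posterior_mean

from conftest import truncated_normal


class TestEstimateBackground:
    def test_recovers_truncated_normal_parameters(self):
        rng = np.random.default_rng(0)
        x = truncated_normal(rng, 500.0, 100.0, 10_000)
        fit = estimate_background(x)
        # 3x asymptotic SE ~ 3*sigma/sqrt(n) = 3
        assert fit.mu == pytest.approx(500.0, abs=10.0)
        assert fit.sigma == pytest.approx(100.0, abs=10.0)

    def test_constant_values_are_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_background(np.full(200, 7.0))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="100"):
            estimate_background(np.arange(50.0))

    def test_negligible_truncation_matches_plain_mle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1000.0, 100.0, 20_000)  # 10 sigma above zero
        fit = estimate_background(x)
        assert fit.mu == pytest.approx(float(x.mean()), rel=0.01)
        assert fit.sigma == pytest.approx(float(x.std(ddof=1)), rel=0.01)


def simulate_model(rng, n, pi, lam, mu_s, sigma_s, bg_mu, bg_sd):
    bg = truncated_normal(rng, bg_mu, bg_sd, n)
    z = rng.random(n) < pi
    s = np.where(
        z, rng.exponential(1.0 / lam, n), truncated_normal(rng, mu_s, sigma_s, n)
    )
    return s + bg


class TestSignalMixtureEM:
    def test_parameter_recovery_within_ten_percent(self):
        rng = np.random.default_rng(42)
        x = simulate_model(rng, 50_000, 0.3, 1 / 3000, 8000.0, 1500.0, 300.0, 50.0)
        bg = estimate_background(truncated_normal(rng, 300.0, 50.0, 10_000))
        fit = fit_signal_mixture(x, bg)
        assert fit.pi_exp == pytest.approx(0.3, rel=0.10)
        assert 1 / fit.lam == pytest.approx(3000.0, rel=0.10)
        assert fit.mu_s == pytest.approx(8000.0, rel=0.10)
        assert fit.sigma_s == pytest.approx(1500.0, rel=0.10)

    def test_pure_exponential_boundary(self):
        rng = np.random.default_rng(7)
        bg_true = TruncNormParams(300.0, 50.0)
        x = truncated_normal(rng, 300.0, 50.0, 20_000) + rng.exponential(3000.0, 20_000)
        # the mixture-weight boundary is a slow-convergence regime: the
        # truncated normal sheds its weight gradually, so use a tight
        # stopping tolerance for the recovery check
        fit = fit_signal_mixture(x, bg_true, tol=1e-6, max_iter=1000)
        assert fit.pi_exp >= 0.95

    def test_loglik_trace_non_decreasing(self):
        rng = np.random.default_rng(9)
        x = simulate_model(rng, 5_000, 0.5, 1 / 2000, 6000.0, 1000.0, 300.0, 50.0)
        fit = fit_signal_mixture(x, TruncNormParams(300.0, 50.0))
        deltas = np.diff(fit.loglik_trace)
        assert (deltas > -1e-8).all()

    def test_too_few_intensities_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            fit_signal_mixture(np.arange(500.0), TruncNormParams(300.0, 50.0))


def convolution_posterior_mean_oracle(x, model):
    """E[S | X=x] by direct numerical integration, independent of the
    package's Gauss-Legendre machinery."""
    bg, sig = model.bg, model.sig
    norm_b = stats.norm(bg.mu, bg.sigma)
    cb = 1.0 - norm_b.cdf(0.0)
    norm_s = stats.norm(sig.mu_s, sig.sigma_s)
    cs = 1.0 - norm_s.cdf(0.0)

    def f_s(s):
        return sig.pi_exp * sig.lam * np.exp(-sig.lam * s) + (
            1.0 - sig.pi_exp
        ) * norm_s.pdf(s) / cs

    def integrand_den(s):
        return f_s(s) * norm_b.pdf(x - s) / cb

    def integrand_num(s):
        return s * integrand_den(s)

    den, _ = integrate.quad(integrand_den, 0, x, limit=500)
    num, _ = integrate.quad(integrand_num, 0, x, limit=500)
    return num / den


class TestCorrection:
    MODEL = BackgroundModel(
        TruncNormParams(300.0, 50.0),
        SignalMixtureParams(0.3, 1 / 3000, 8000.0, 1500.0),
    )

    def test_matches_quadrature_oracle(self):
        xs = np.linspace(500.0, 20_000.0, 20)
        ours = correct_intensities(xs, self.MODEL)
        oracle = np.array([convolution_posterior_mean_oracle(x, self.MODEL) for x in xs])
        assert np.max(np.abs(ours - oracle) / oracle) < 1e-3

    def test_pure_exponential_limit_matches_normexp_closed_form(self):
        model = BackgroundModel(
            TruncNormParams(300.0, 50.0),
            SignalMixtureParams(1.0 - 1e-12, 1 / 3000, 8000.0, 1500.0),
        )
        xs = np.linspace(600.0, 20_000.0, 20)
        ours = correct_intensities(xs, model)
        closed = _normexp_posterior_mean(xs, NormexpParams(300.0, 50.0, 3000.0))
        assert np.max(np.abs(ours - closed) / closed) < 1e-4

    def test_zero_input_floored(self):
        assert correct_intensities(np.array([0.0]), self.MODEL)[0] == 1.0

    def test_strictly_increasing_on_grid(self):
        grid = np.linspace(10.0, 30_000.0, 400)
        c = correct_intensities(grid, self.MODEL)
        assert (np.diff(c[c > 1.0]) > 0).all()

    def test_background_subtraction_regime_far_from_background(self):
        bg = self.MODEL.bg
        xs = np.linspace(bg.mu + 6 * bg.sigma, 30_000.0, 50)
        c = correct_intensities(xs, self.MODEL)
        assert (c <= xs).all()
        assert (c >= xs - bg.mu - 3 * bg.sigma).all()

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            correct_intensities(np.array([-1.0]), self.MODEL)
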