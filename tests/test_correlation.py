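"""Covariance estimation, the 21-function bookkeeping, and multiexponential fits."""

import numpy as np
import pytest

from lipidspin.correlation import (
    LAG_GRID_NS,
    CovarianceCurve,
    CovarianceModel,
    ScalarSeries,
    distinct_component_pairs,
    effective_correlation_time,
    fit_covariance_model,
    load_curve,
    load_model,
    model_curve,
    save_curve,
    save_model,
    series_covariance,
    spectral_density,
    spectral_density_zero,
)


def _direct_covariance(x, y, n_lags):
    """O(N^2) reference estimator used as the brute-force oracle."""
    dx = x - x.mean()
    dy = y - y.mean()
    n = len(x)
    out = np.zeros(n_lags)
    for k in range(n_lags):
        for t in range(k, n):
            out[k] += dx[t] * dy[t - k]
    return out / n


class TestSeriesCovariance:
    def test_fft_matches_direct_sum(self, rng):
        x = ScalarSeries(rng.normal(size=2000), dt_ps=1.0)
        y = ScalarSeries(rng.normal(size=2000) + 0.5 * x.values, dt_ps=1.0)
        for a, b in [(x, x), (x, y), (y, x)]:
            curve = series_covariance(a, b, max_lag_ns=0.05)
            ref = _direct_covariance(a.values, b.values, curve.values.size)
            np.testing.assert_allclose(curve.values, ref, atol=1e-10)

    def test_constant_series_is_zero(self):
        x = ScalarSeries(np.full(5000, 3.7))
        curve = series_covariance(x, max_lag_ns=1.0)
        np.testing.assert_allclose(curve.values, 0.0, atol=1e-12)

    def test_alternating_series_normalized(self):
        n = 4000
        x = ScalarSeries(np.tile([1.0, -1.0], n // 2))
        curve = series_covariance(x, max_lag_ns=0.01).normalize()
        k = np.arange(curve.values.size)
        # the biased 1/N estimator gives exactly (-1)^k (N-k)/N -> (-1)^k
        np.testing.assert_allclose(curve.values, (-1.0) ** k * (n - k) / n, atol=1e-12)
        np.testing.assert_allclose(curve.values, (-1.0) ** k, atol=5e-3)

    def test_lag_grid_and_errors(self, rng):
        x = ScalarSeries(rng.normal(size=1000))
        curve = series_covariance(x, max_lag_ns=0.2)
        assert curve.lags_ns[0] == 0.0
        assert curve.sigma2 == pytest.approx(x.values.var(), rel=1e-10)
        with pytest.raises(ValueError, match="length"):
            series_covariance(x, ScalarSeries(rng.normal(size=999)), max_lag_ns=0.1)
        with pytest.raises(ValueError, match="span"):
            series_covariance(x, max_lag_ns=2.0)


class TestDistinctPairs:
    def test_symmetric_tensor_has_21_distinct_functions(self):
        assert len(distinct_component_pairs(symmetric=True)) == 21

    def test_six_pure_autocovariances(self):
        pairs = distinct_component_pairs(symmetric=True)
        autos = [p for p in pairs if p[0] == p[1]]
        assert len(autos) == 6

    def test_without_symmetry_45_classes(self):
        assert len(distinct_component_pairs(symmetric=False)) == 45


class TestLagGrid:
    def test_grid_endpoints_and_monotonicity(self):
        assert LAG_GRID_NS.size == 50
        assert LAG_GRID_NS[0] == 5e-4
        assert LAG_GRID_NS[-1] == 100.0
        assert np.all(np.diff(LAG_GRID_NS) > 0)


def _curve_from_mixture(weights, taus, sigma2=1.0, max_lag=50.0, dt=0.001):
    lags = np.arange(0.0, max_lag + dt, dt)
    vals = sigma2 * sum(w * np.exp(-lags / t) for w, t in zip(weights, taus))
    return CovarianceCurve(lags, vals, sigma2=sigma2)


class TestFit:
    def test_single_exponential_recovery(self):
        curve = _curve_from_mixture([1.0], [1.0])
        model = fit_covariance_model(curve)
        assert effective_correlation_time(model) == pytest.approx(1.0, rel=0.02)

    def test_two_mode_mixture(self):
        curve = _curve_from_mixture([0.5, 0.5], [0.1, 2.0])
        model = fit_covariance_model(curve)
        assert effective_correlation_time(model) == pytest.approx(1.05, rel=0.05)

    def test_white_noise_curve(self):
        lags = np.arange(0.0, 20.0, 0.001)
        vals = np.zeros(lags.size)
        vals[0] = 2.0
        model = fit_covariance_model(CovarianceCurve(lags, vals, sigma2=2.0))
        assert effective_correlation_time(model) <= 2 * LAG_GRID_NS[0]

    def test_exact_recovery_of_grid_mixtures(self, rng):
        for _ in range(5):
            idx = rng.choice(np.arange(10, 45), size=3, replace=False)
            w = rng.dirichlet(np.ones(3))
            curve = _curve_from_mixture(w, LAG_GRID_NS[idx], sigma2=3.0)
            model = fit_covariance_model(curve)
            assert model.residual_rms < 0.02  # of the normalized (sigma2=1) curve
            tau_true = float(w @ LAG_GRID_NS[idx])
            assert effective_correlation_time(model) == pytest.approx(tau_true, rel=0.02)

    def test_effective_time_invariant_under_rescaling(self):
        c1 = _curve_from_mixture([1.0], [0.5], sigma2=1.0)
        c2 = _curve_from_mixture([1.0], [0.5], sigma2=42.0)
        t1 = effective_correlation_time(fit_covariance_model(c1))
        t2 = effective_correlation_time(fit_covariance_model(c2))
        assert t1 == pytest.approx(t2, rel=1e-6)

    def test_degenerate_zero_curve(self):
        lags = np.arange(0.0, 20.0, 0.01)
        model = fit_covariance_model(CovarianceCurve(lags, np.zeros(lags.size), sigma2=0.0))
        assert model.degenerate
        assert model.prefactor == 0.0
        assert model.weights.sum() == pytest.approx(1.0)

    def test_short_curve_rejected(self):
        lags = np.arange(0.0, 5.0, 0.01)
        with pytest.raises(ValueError, match="lag"):
            fit_covariance_model(CovarianceCurve(lags, np.exp(-lags), sigma2=1.0))

    def test_weight_constraints(self):
        curve = _curve_from_mixture([0.7, 0.3], [0.05, 1.0])
        model = fit_covariance_model(curve)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(model.weights >= 0)


class TestEffectiveTimeAndSpectralDensity:
    def test_point_mass_and_uniform_weights(self):
        w = np.zeros(50)
        w[30] = 1.0
        m = CovarianceModel(1.0, w)
        assert effective_correlation_time(m) == pytest.approx(LAG_GRID_NS[30])
        m_uniform = CovarianceModel(1.0, np.full(50, 0.02))
        assert effective_correlation_time(m_uniform) == pytest.approx(LAG_GRID_NS.mean())

    def test_effective_time_equals_curve_integral(self):
        curve = _curve_from_mixture([0.4, 0.6], [0.3, 1.5], max_lag=40.0)
        model = fit_covariance_model(curve, max_fit_lag_ns=40.0)
        lags = np.linspace(0.0, 400.0, 400001)
        integral = np.trapezoid(model_curve(model, lags) / model.prefactor, lags)
        assert effective_correlation_time(model) == pytest.approx(integral, rel=0.01)

    def test_j0_arithmetic(self):
        w = np.zeros(50)
        j = int(np.argmin(np.abs(LAG_GRID_NS - 0.5)))
        w[j] = 1.0
        m = CovarianceModel(4.0, w)
        assert spectral_density_zero(m) == pytest.approx(4.0 * LAG_GRID_NS[j])
        assert spectral_density_zero(CovarianceModel(0.0, w)) == 0.0

    def test_j0_equals_one_sided_fourier_integral_at_zero(self):
        curve = _curve_from_mixture([1.0], [0.8], sigma2=2.5, max_lag=40.0)
        model = fit_covariance_model(curve, max_fit_lag_ns=40.0)
        lags = np.linspace(0.0, 400.0, 400001)
        integral = np.trapezoid(model_curve(model, lags), lags)
        assert spectral_density_zero(model) == pytest.approx(integral, rel=0.01)

    def test_lorentzian_spectral_density_limits(self):
        w = np.zeros(50)
        w[25] = 1.0
        m = CovarianceModel(2.0, w)
        tau = LAG_GRID_NS[25]
        assert spectral_density(m, 0.0) == pytest.approx(spectral_density_zero(m))
        assert spectral_density(m, 1.0 / tau) == pytest.approx(spectral_density_zero(m) / 2)

    def test_g_channel_bilinearity(self):
        w = np.zeros(50)
        w[20] = 1.0
        j1 = spectral_density_zero(CovarianceModel(1e-4, w))
        j2 = spectral_density_zero(CovarianceModel(3e-4, w))
        assert j2 == pytest.approx(3 * j1)


class TestSerialization:
    def test_model_roundtrip(self, tmp_path):
        curve = _curve_from_mixture([0.5, 0.5], [0.2, 2.0], sigma2=1.7)
        model = fit_covariance_model(curve, pair=("xy", "zz"))
        path = tmp_path / "model.yaml"
        save_model(model, path)
        back = load_model(path)
        assert back.pair == ("xy", "zz")
        assert back.prefactor == pytest.approx(model.prefactor)
        np.testing.assert_allclose(back.weights, model.weights, atol=1e-12)
        np.testing.assert_allclose(back.lag_grid_ns, model.lag_grid_ns, rtol=1e-12)

    def test_curve_roundtrip(self, tmp_path):
        curve = _curve_from_mixture([1.0], [0.5], sigma2=2.0, max_lag=15.0, dt=0.01)
        path = tmp_path / "curve.tsv"
        save_curve(curve, path)
        back = load_curve(path)
        np.testing.assert_allclose(back.values, curve.values, rtol=1e-10)
        assert back.sigma2 == pytest.approx(curve.sigma2)
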