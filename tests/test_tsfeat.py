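"""Feature catalog, ACF/DFA primitives, normalization and aggregation."""

import numpy as np
import pandas as pd
import pytest

from megdyn.containers import FeatureMatrix
from megdyn.tsfeat import (
    acf_at_lag,
    acf_first_zero,
    aggregate_group,
    compute_feature_vector,
    default_catalog,
    dfa,
    fast_catalog,
    normalize_feature_matrix,
    robust_sigmoid,
    rolling_linear_forecast_residuals,
    sample_acf,
    stability_curve,
)


class TestCatalog:
    def test_catalog_shape_and_families(self):
        cat = default_catalog()
        names = [d.name for d in cat]
        assert len(names) == len(set(names))
        assert len(cat) >= 100
        assert {d.family for d in cat} == {
            "distribution", "autocorrelation", "forecasting",
            "fluctuation", "wavelet", "entropy", "spectral",
        }
        assert set(d.name for d in fast_catalog()) <= set(names)

    def test_gaussian_moments(self, white_noise):
        cat = default_catalog()
        vals, valid = compute_feature_vector(white_noise, 500.0, cat)
        by_name = dict(zip([d.name for d in cat], vals))
        assert abs(by_name["dist_skewness"]) < 0.1
        assert abs(by_name["dist_kurtosis"]) < 0.1

    def test_linear_ramp_forecast_residual_zero(self):
        ramp = np.linspace(0.0, 1.0, 2000)
        res = rolling_linear_forecast_residuals(ramp, 5)
        assert np.max(np.abs(res)) < 1e-9

    def test_deterministic(self, white_noise):
        v1, m1 = compute_feature_vector(white_noise, 500.0)
        v2, m2 = compute_feature_vector(white_noise, 500.0)
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_array_equal(m1, m2)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            compute_feature_vector(np.zeros(100), 500.0)

    def test_correlation_features_scale_invariant(self, white_noise):
        cat = [d for d in default_catalog() if d.family == "autocorrelation"]
        x = white_noise[:10000]
        v1, m1 = compute_feature_vector(x, 500.0, cat)
        v2, m2 = compute_feature_vector(3.7 * x + 11.0, 500.0, cat)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_allclose(v1[m1], v2[m1], rtol=1e-8, atol=1e-10)


class TestACF:
    def test_alternating_signal_crosses_at_one(self):
        x = np.tile([1.0, -1.0], 500)
        steps, secs = acf_first_zero(x, 100.0)
        assert steps == 1
        assert secs == pytest.approx(0.01)

    def test_cosine_crosses_near_quarter_period(self):
        t = np.arange(50000)
        x = np.cos(2 * np.pi * t / 200.0)  # period 200 samples
        steps, _ = acf_first_zero(x, 1.0, max_lag_s=300.0)
        # brute-force oracle on the sampled cosine
        acf = sample_acf(x, 120)
        oracle = int(np.flatnonzero(acf[1:] <= 0)[0] + 1)
        assert steps == oracle
        assert abs(steps - 50) <= 1  # ~ T/4

    def test_ramp_does_not_cross(self):
        steps, secs = acf_first_zero(np.arange(3000.0), 100.0, max_lag_s=0.1)
        assert steps is None and secs is None

    def test_lag_zero_is_unity(self, white_noise):
        assert acf_at_lag(white_noise, 500.0, 0.0) == pytest.approx(1.0)

    def test_ar1_theory(self):
        rng = np.random.default_rng(3)
        x = np.empty(40000)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(40000)
        for i in range(1, 40000):
            x[i] = 0.9 * x[i - 1] + eps[i]
        got = acf_at_lag(x, 500.0, 48e-3)  # 24 steps at 500 Hz
        assert abs(got - 0.9**24) < 0.03

    def test_white_noise_long_lag_near_zero(self, white_noise):
        assert abs(acf_at_lag(white_noise, 500.0, 48e-3)) < 0.02

    def test_constant_signal_invalid(self):
        with pytest.raises(ValueError):
            acf_at_lag(np.ones(1000), 100.0, 0.01)


class TestDFA:
    def test_white_noise_alpha_half(self):
        alphas = []
        for s in range(20):
            x = np.random.default_rng(100 + s).standard_normal(40000)
            alphas.append(dfa(x).alpha)
        assert abs(np.median(alphas) - 0.5) < 0.05

    def test_brownian_alpha_three_halves(self):
        alphas = []
        for s in range(20):
            x = np.cumsum(np.random.default_rng(200 + s).standard_normal(40000))
            alphas.append(dfa(x).alpha)
        assert abs(np.median(alphas) - 1.5) < 0.1

    def test_perfectly_detrendable_profile_invalid(self):
        # a line's cumulative profile is quadratic: order-2 windows remove
        # it exactly, so fluctuations vanish and the result is flagged
        r = dfa(np.linspace(0, 1, 4000), detrend_order=2)
        assert not r.valid
        assert np.isnan(r.alpha)
        r0 = dfa(np.zeros(4000), detrend_order=1)
        assert not r0.valid

    def test_scale_bounds_enforced(self):
        with pytest.raises(ValueError):
            dfa(np.random.default_rng(0).standard_normal(1000), scales=[2, 4, 8])

    def test_abs_formulation_close_to_rms(self):
        x = np.random.default_rng(7).standard_normal(20000)
        a1 = dfa(x, formulation="rms").alpha
        a2 = dfa(x, formulation="abs").alpha
        assert abs(a1 - a2) < 0.1


class TestNormalization:
    def test_median_maps_to_half_before_rescale(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        med, iqr = np.median(x), np.quantile(x, 0.75) - np.quantile(x, 0.25)
        norm = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
        assert norm[2] == pytest.approx(0.5)

    def test_rescale_endpoints(self):
        scaled, ok = robust_sigmoid(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
        assert ok
        assert scaled.min() == pytest.approx(0.0)
        assert scaled.max() == pytest.approx(1.0)

    def test_hand_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        med = np.median(x)
        iqr = (np.quantile(x, 0.75) - np.quantile(x, 0.25)) / 1.35
        norm = 1.0 / (1.0 + np.exp(-(x - med) / iqr))
        expect = (norm - norm.min()) / (norm.max() - norm.min())
        scaled, _ = robust_sigmoid(x, iqr_norm=1.35)
        np.testing.assert_allclose(scaled, expect, rtol=1e-12)

    def test_monotone(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        scaled, _ = robust_sigmoid(x)
        assert np.array_equal(np.argsort(x), np.argsort(scaled))

    def test_constant_feature_flagged(self):
        fm = FeatureMatrix(pd.DataFrame({
            "a": [1.0, 2.0, 3.0, 4.0],
            "b": [5.0, 5.0, 5.0, 5.0],
        }))
        out = normalize_feature_matrix(fm)
        assert out.mask["a"].all()
        assert not out.mask["b"].any()
        assert out.normalization == "sigmoid-scaled"


class TestAggregation:
    def _fm(self, vals, mask=None, participant="s"):
        df = pd.DataFrame(vals, columns=["f1", "f2"])
        m = None if mask is None else pd.DataFrame(mask, columns=["f1", "f2"])
        return FeatureMatrix(df, m, participant=participant)

    def test_single_participant_identity(self):
        fm = self._fm([[1.0, 2.0], [3.0, 4.0]])
        out = aggregate_group([fm])
        pd.testing.assert_frame_equal(out.values, fm.values)

    def test_invalid_anywhere_dropped_everywhere(self):
        a = self._fm([[1.0, 2.0], [3.0, 4.0]])
        b = self._fm([[1.0, np.nan], [3.0, 4.0]],
                     mask=[[True, False], [True, True]])
        out = aggregate_group([a, b])
        assert out.feature_names == ["f1"]

    def test_mean_of_opposites_is_zero(self):
        a = self._fm([[1.0, -2.0], [3.0, 4.0]])
        b = self._fm([[-1.0, 2.0], [-3.0, -4.0]])
        out = aggregate_group([a, b])
        assert (out.values.to_numpy() == 0).all()

    def test_empty_intersection_aborts(self):
        a = self._fm([[1.0, 2.0], [3.0, 4.0]],
                     mask=[[False, True], [True, True]])
        b = self._fm([[1.0, 2.0], [3.0, 4.0]],
                     mask=[[True, False], [True, True]])
        with pytest.raises(RuntimeError):
            aggregate_group([a, b])


class TestGradientMonotonicity:
    def test_long_lag_acf_and_dfa_track_latent_gradient(self, geometry):
        """Slower-knee regions show higher long-lag ACF and DFA alpha."""
        from scipy.stats import spearmanr

        from megdyn.synthgen import AperiodicProfile, gen_regional_timeseries

        latent = np.linspace(-1.0, 1.0, geometry.n_parcels)
        # knee falls along the gradient -> slower dynamics -> more memory;
        # knees chosen so tau (24-72 ms) brackets the 48 ms probe lag
        profile = AperiodicProfile(offset=0.0, knee=25.0, exponent=2.0,
                                   knee_slope=-20.0)
        ts = gen_regional_timeseries(geometry, 60.0, 509.0,
                                     aperiodic_profile=profile, seed=55,
                                     latent_map=latent)
        ac24, alpha = [], []
        for r in range(geometry.n_parcels):
            x = ts.data[0, r]
            ac24.append(acf_at_lag(x, ts.fs, 48e-3))
            alpha.append(dfa(x).alpha)
        assert spearmanr(ac24, latent).statistic > 0.8
        assert spearmanr(alpha, latent).statistic > 0.8


class TestStability:
    def test_periodic_signal_perfect_stability(self):
        fs = 200.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 5.0 * t)
        curve = stability_curve(x, fs, lengths_s=[5, 10, 15, 20, 25, 30])
        assert np.all(curve["r"].to_numpy() > 0.999)

    def test_stationary_signal_stabilizes(self):
        rng = np.random.default_rng(9)
        fs = 200.0
        # AR(1) noise, stationary
        x = np.empty(int(130 * fs))
        x[0] = 0.0
        eps = rng.standard_normal(x.size)
        for i in range(1, x.size):
            x[i] = 0.95 * x[i - 1] + eps[i]
        curve = stability_curve(x, fs)
        r = curve["r"].to_numpy()
        assert np.nanmean(r[-5:]) > np.nanmean(r[:3])
        assert np.nanmean(r[-5:]) > 0.95

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            stability_curve(np.random.default_rng(0).standard_normal(500),
                            200.0, lengths_s=[5, 10])
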