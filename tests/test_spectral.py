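"""Spectral estimation and parameterization against closed forms and oracles."""

import numpy as np
import pytest

from megdyn.spectral import (
    ADJUSTED_BANDS,
    BandDefinition,
    PSDEstimate,
    SpectralModelFit,
    SpectralPeak,
    TOTAL_POWER_BANDS,
    band_power,
    fit_spectral_model,
    knee_frequency_and_timescale,
    oscillation_score,
    welch_psd,
)


class TestWelch:
    def test_constant_signal_no_power(self):
        psd = welch_psd((np.full((1, 2000), 3.0), 100.0), window_s=4.0)
        assert np.all(psd.power[0][psd.frequencies > 0] < 1e-20)

    def test_parseval_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(80 * 500)
        psd = welch_psd((x, 500.0), window_s=4.0)
        total = np.trapezoid(psd.power[0], psd.frequencies)
        assert abs(total - x.var()) < 0.05

    def test_sinusoid_peak_bin(self):
        t = np.arange(20000) / 500.0
        x = np.sin(2 * np.pi * 10.0 * t)
        psd = welch_psd((x, 500.0), window_s=4.0)
        assert psd.frequencies[np.argmax(psd.power[0])] == pytest.approx(10.0)

    def test_window_longer_than_signal(self):
        with pytest.raises(ValueError):
            welch_psd((np.zeros((1, 100)), 100.0), window_s=4.0)


class TestBandPower:
    def _flat_psd(self, value=2.5):
        f = np.arange(0, 100.25, 0.25)
        return PSDEstimate(f, np.full((1, f.size), value), 4.0, 0.5, 200.0)

    def test_flat_psd_returns_constant(self):
        bp = band_power(self._flat_psd(2.5))
        for band in TOTAL_POWER_BANDS:
            assert bp[band.name][0] == pytest.approx(2.5)

    def test_support_restriction(self):
        f = np.arange(0, 100.25, 0.25)
        p = np.zeros((1, f.size))
        p[0, (f >= 8) & (f <= 12)] = 1.0
        psd = PSDEstimate(f, p, 4.0, 0.5, 200.0)
        bp = band_power(psd)
        assert bp["alpha"][0] > 0
        for name in ("delta", "theta", "beta", "lo_gamma", "hi_gamma"):
            assert bp[name][0] == 0.0

    def test_matches_loop_oracle(self):
        f = np.arange(0, 100.25, 0.25)
        lorentz = 1.0 / (1.0 + (f / 10.0) ** 2)
        psd = PSDEstimate(f, lorentz[None, :], 4.0, 0.5, 200.0)
        bp = band_power(psd)
        for band in TOTAL_POWER_BANDS:
            acc, cnt = 0.0, 0
            for i in range(f.size):  # independent loop-based average
                if band.lo <= f[i] <= band.hi:
                    acc += lorentz[i]
                    cnt += 1
            assert bp[band.name][0] == pytest.approx(acc / cnt)

    def test_band_outside_grid(self):
        with pytest.raises(ValueError):
            band_power(self._flat_psd(), (BandDefinition("uhf", 500, 600),))

    def test_linearity(self):
        f = np.arange(0, 100.25, 0.25)
        rng = np.random.default_rng(1)
        p1 = rng.random(f.size)[None, :]
        p2 = rng.random(f.size)[None, :]
        a = 3.7
        lhs = band_power(PSDEstimate(f, a * p1 + p2, 4.0, 0.5, 200.0))
        b1 = band_power(PSDEstimate(f, p1, 4.0, 0.5, 200.0))
        b2 = band_power(PSDEstimate(f, p2, 4.0, 0.5, 200.0))
        for band in TOTAL_POWER_BANDS:
            assert lhs[band.name][0] == pytest.approx(a * b1[band.name][0] + b2[band.name][0])


class TestSpectralModel:
    f = np.arange(1.0, 60.25, 0.25)

    def test_noiseless_aperiodic_recovery(self):
        power = 10.0 ** (0.0 - np.log10(100.0 + self.f**2.0))
        fit = fit_spectral_model(self.f, power)
        assert abs(fit.knee - 100.0) / 100.0 < 0.02
        assert abs(fit.exponent - 2.0) / 2.0 < 0.02
        assert len(fit.peaks) == 0

    def test_single_peak_recovery(self):
        logp = -np.log10(100.0 + self.f**2.0)
        logp += 0.5 * np.exp(-((self.f - 10.0) ** 2) / (2 * 2.0**2))
        fit = fit_spectral_model(self.f, 10.0**logp)
        assert len(fit.peaks) == 1
        assert abs(fit.peaks[0].center - 10.0) < 0.5
        # aperiodic refit on the peak-removed spectrum stays near truth
        assert abs(fit.knee - 100.0) / 100.0 < 0.15
        assert abs(fit.exponent - 2.0) / 2.0 < 0.05

    def test_max_peak_cap(self):
        logp = -np.log10(10.0 + self.f**1.5)
        centers = [5, 11, 17, 23, 29, 35, 41, 47]
        for c in centers:
            logp = logp + 0.6 * np.exp(-((self.f - c) ** 2) / (2 * 1.0**2))
        fit = fit_spectral_model(self.f, 10.0**logp)
        assert len(fit.peaks) <= 6

    def test_invalid_fit_range(self):
        with pytest.raises(ValueError):
            fit_spectral_model(self.f, np.ones_like(self.f), fit_lo=0.0)

    def test_nonpositive_power_rejected(self):
        p = np.ones_like(self.f)
        p[10] = 0.0
        with pytest.raises(ValueError):
            fit_spectral_model(self.f, p)


class TestKneeTimescale:
    @pytest.mark.parametrize(
        "k,chi,fk,tau",
        [
            (100.0, 2.0, 10.0, 1.0 / (20 * np.pi)),
            (1.0, 3.7, 1.0, 1.0 / (2 * np.pi)),
            (8.0, 3.0, 2.0, 1.0 / (4 * np.pi)),
        ],
    )
    def test_closed_forms(self, k, chi, fk, tau):
        fit = SpectralModelFit(0.0, k, chi, [], r_squared=1.0)
        got_fk, got_tau = knee_frequency_and_timescale(fit)
        assert got_fk == pytest.approx(fk, rel=1e-12)
        assert got_tau == pytest.approx(tau, rel=1e-12)

    def test_undefined_flag(self):
        fit = SpectralModelFit(0.0, -1.0, 2.0, [], r_squared=1.0)
        fk, tau = knee_frequency_and_timescale(fit)
        assert np.isnan(fk) and np.isnan(tau)

    def test_monotonicity(self):
        # f_k increasing in k at fixed chi; tau decreasing in f_k
        ks = np.linspace(1, 500, 25)
        fks = [knee_frequency_and_timescale(SpectralModelFit(0, k, 2.0, []))[0] for k in ks]
        taus = [knee_frequency_and_timescale(SpectralModelFit(0, k, 2.0, []))[1] for k in ks]
        assert np.all(np.diff(fks) > 0)
        assert np.all(np.diff(taus) < 0)


def _fit_with_peaks(*peaks):
    return SpectralModelFit(0.0, 100.0, 2.0, list(peaks), r_squared=1.0)


class TestOscillationScore:
    def test_uniform_peaks_score_one(self):
        fits = [
            [_fit_with_peaks(SpectralPeak(10.0, 1.0, 2.0)) for _ in range(4)]
            for _ in range(3)
        ]
        osc = oscillation_score(fits, ADJUSTED_BANDS)
        np.testing.assert_allclose(osc["alpha"].score, 1.0)

    def test_no_detection_scores_zero(self):
        fits = [
            [_fit_with_peaks(SpectralPeak(10.0, 1.0, 2.0)), _fit_with_peaks()]
            for _ in range(2)
        ]
        osc = oscillation_score(fits, ADJUSTED_BANDS)
        assert osc["alpha"].score[1] == 0.0

    def test_hand_worked_example(self):
        # parcel A: peak powers {2, 4} in both participants -> mean 3
        # parcel B: power 8 in one participant only        -> mean 8
        # normalized (0.375, 1), probabilities (1, 0.5), scores (0.375, 0.5)
        fits = [
            [_fit_with_peaks(SpectralPeak(10, 2.0, 2.0)),
             _fit_with_peaks(SpectralPeak(10, 8.0, 2.0))],
            [_fit_with_peaks(SpectralPeak(10, 4.0, 2.0)),
             _fit_with_peaks()],
        ]
        osc = oscillation_score(fits, ADJUSTED_BANDS)
        np.testing.assert_allclose(osc["alpha"].normalized_power, [0.375, 1.0])
        np.testing.assert_allclose(osc["alpha"].probability, [1.0, 0.5])
        np.testing.assert_allclose(osc["alpha"].score, [0.375, 0.5])

    def test_max_power_peak_selected(self):
        fits = [[_fit_with_peaks(SpectralPeak(9, 1.0, 2.0), SpectralPeak(11, 3.0, 2.0))]]
        osc = oscillation_score(fits, ADJUSTED_BANDS)
        assert osc["alpha"].normalized_power[0] == 1.0  # max (3.0) normalizes itself


class TestRoundTrip:
    def test_knee_gradient_ordering_recovered(self, geometry):
        """A knee gradient across regions is recovered in rank order."""
        from megdyn.synthgen import AperiodicProfile, gen_regional_timeseries
        from scipy.stats import spearmanr

        latent = np.linspace(-1, 1, geometry.n_parcels)
        profile = AperiodicProfile(offset=0.0, knee=150.0, exponent=2.0, knee_slope=100.0)
        ts = gen_regional_timeseries(
            geometry, 40.0, 509.0, aperiodic_profile=profile, seed=77,
            latent_map=latent,
        )
        psd = welch_psd(ts)
        taus = []
        for r in range(geometry.n_parcels):
            fit = fit_spectral_model(psd.frequencies, psd.power[r])
            taus.append(knee_frequency_and_timescale(fit)[1])
        _, k, chi = profile.per_region(latent)
        true_tau = 1.0 / (2 * np.pi * k ** (1.0 / chi))
        rho = spearmanr(taus, true_tau).statistic
        assert rho > 0.8
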