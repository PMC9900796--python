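"""Power spectra, aperiodic-knee model fitting, and intrinsic timescale.

PSDs come from Welch's method (4 s Hann windows, 50% overlap by default).
The spectral parameterization decomposes a log10 power spectrum into an
aperiodic component ``b - log10(k + f**chi)`` (offset b, knee k, exponent
chi) and Gaussian oscillatory peaks, iteratively: robust aperiodic fit,
peak extraction largest-first from the flattened residual, then aperiodic
refit on the peak-removed spectrum. The knee frequency is ``f_k =
k**(1/chi)`` and the intrinsic timescale ``tau = 1 / (2 pi f_k)``.

Oscillation scores summarize group-level band-limited peaks: the group
mean peak power map (over participants with a detected peak), normalized
to its max over parcels, times the detection-probability map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import least_squares

from .containers import RegionalTimeSeriesSet

__all__ = [
    "PSDEstimate",
    "SpectralPeak",
    "SpectralModelFit",
    "BandDefinition",
    "TOTAL_POWER_BANDS",
    "ADJUSTED_BANDS",
    "welch_psd",
    "band_power",
    "fit_spectral_model",
    "fit_spectra",
    "knee_frequency_and_timescale",
    "oscillation_score",
    "OscillationScoreMap",
]


@dataclass
class PSDEstimate:
    frequencies: np.ndarray
    power: np.ndarray  # (n_regions, n_freqs), one-sided density
    window_s: float
    overlap: float
    fs: float

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")


# canonical electrophysiological bands for total power
TOTAL_POWER_BANDS = (
    BandDefinition("delta", 2, 4),
    BandDefinition("theta", 5, 7),
    BandDefinition("alpha", 8, 12),
    BandDefinition("beta", 15, 29),
    BandDefinition("lo_gamma", 30, 59),
    BandDefinition("hi_gamma", 60, 90),
)

# bands for aperiodic-adjusted (peak-based) power; gamma excluded because
# consistent spectral peaks are not detectable at gamma frequencies
ADJUSTED_BANDS = (
    BandDefinition("delta", 2, 4),
    BandDefinition("theta", 5, 7),
    BandDefinition("alpha", 8, 14),
    BandDefinition("beta", 15, 30),
)


def welch_psd(
    ts, window_s: float = 4.0, overlap: float = 0.5, participant: int = None
) -> PSDEstimate:
    """Welch PSD per region (one-sided density, Hann taper).

    ``ts`` may be a RegionalTimeSeriesSet (pass ``participant`` to select
    one, default 0) or a (regions x samples) array plus ``ts.fs``-style
    handling via a tuple ``(array, fs)``.
    """
    if isinstance(ts, RegionalTimeSeriesSet):
        data = ts.data[participant if participant is not None else 0]
        fs = ts.fs
    else:
        data, fs = ts
        data = np.atleast_2d(np.asarray(data, dtype=float))
    nperseg = int(round(window_s * fs))
    if nperseg > data.shape[-1]:
        raise ValueError("window longer than signal")
    freqs, power = sps.welch(
        data, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)), detrend="constant", axis=-1,
    )
    return PSDEstimate(freqs, power, window_s, overlap, fs)


def band_power(psd: PSDEstimate, bands=TOTAL_POWER_BANDS) -> dict:
    """Mean PSD over in-band bins (inclusive bounds) per region per band."""
    out = {}
    for band in bands:
        sel = (psd.frequencies >= band.lo) & (psd.frequencies <= band.hi)
        if not np.any(sel):
            raise ValueError(f"band {band.name} outside frequency grid")
        out[band.name] = psd.power[:, sel].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# spectral parameterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralPeak:
    center: float  # Hz
    height: float  # log10-power units above the aperiodic curve
    width: float   # Hz (Gaussian SD)


@dataclass
class SpectralModelFit:
    offset: float
    knee: float
    exponent: float
    peaks: list = field(default_factory=list)
    fit_range: tuple = (1.0, 60.0)
    r_squared: float = np.nan

    @property
    def valid(self) -> bool:
        return (
            np.isfinite(self.r_squared)
            and self.knee > 0
            and self.exponent > 0
        )

    def aperiodic(self, freqs: np.ndarray) -> np.ndarray:
        """Aperiodic component in log10-power units."""
        return self.offset - np.log10(self.knee + np.asarray(freqs, float) ** self.exponent)

    def model(self, freqs: np.ndarray) -> np.ndarray:
        freqs = np.asarray(freqs, dtype=float)
        m = self.aperiodic(freqs)
        for p in self.peaks:
            m = m + p.height * np.exp(-((freqs - p.center) ** 2) / (2 * p.width**2))
        return m


_LN10 = np.log(10.0)


def _aperiodic_model(params, f):
    b, k, chi = params
    return b - np.log10(k + f**chi)


def _aperiodic_jac(params, f):
    b, k, chi = params
    fx = f**chi
    denom = (k + fx) * _LN10
    J = np.empty((f.size, 3))
    J[:, 0] = 1.0
    J[:, 1] = -1.0 / denom
    J[:, 2] = -fx * np.log(f) / denom
    return J


def _gaussian_sum_jac(params, f):
    J = np.empty((f.size, len(params)))
    for i in range(0, len(params), 3):
        c, h, w = params[i : i + 3]
        g = np.exp(-((f - c) ** 2) / (2 * w**2))
        J[:, i] = h * g * (f - c) / w**2
        J[:, i + 1] = g
        J[:, i + 2] = h * g * (f - c) ** 2 / w**3
    return J


def _fit_aperiodic(f, logp, multi_start=(0.5, 1.5, 2.5)):
    """Bounded nonlinear least squares with multi-start on the exponent."""
    best = None
    f_mid = np.median(f)
    lo = [-np.inf, 1e-8, 1e-3]
    hi = [np.inf, 1e9, 10.0]
    for chi0 in multi_start:
        k0 = float(f_mid**chi0)
        b0 = float(logp[0] + np.log10(k0 + f[0] ** chi0))
        try:
            res = least_squares(
                lambda p: _aperiodic_model(p, f) - logp,
                x0=[b0, k0, chi0],
                jac=lambda p: _aperiodic_jac(p, f),
                bounds=(lo, hi),
                max_nfev=3000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return None
    return best.x


def _fit_aperiodic_robust(f, logp):
    """Aperiodic fit down-weighting peak regions.

    Initial fit on all points, then refit excluding points whose positive
    residual exceeds one median absolute deviation (candidate peaks).
    """
    p0 = _fit_aperiodic(f, logp)
    if p0 is None:
        return None
    resid = logp - _aperiodic_model(p0, f)
    mad = np.median(np.abs(resid - np.median(resid))) + 1e-12
    keep = resid <= np.median(resid) + mad
    if keep.sum() >= 5:
        p1 = _fit_aperiodic(f[keep], logp[keep])
        if p1 is not None:
            return p1
    return p0


def _gaussian_sum(params, f):
    m = np.zeros_like(f)
    for i in range(0, len(params), 3):
        c, h, w = params[i : i + 3]
        m = m + h * np.exp(-((f - c) ** 2) / (2 * w**2))
    return m


def fit_spectral_model(
    freqs: np.ndarray,
    power: np.ndarray,
    fit_lo: float = 1.0,
    fit_hi: float = 60.0,
    peak_width_limits: tuple = (1.0, 6.0),
    max_n_peaks: int = 6,
    min_peak_height: float = 0.1,
    peak_threshold: float = 2.0,
) -> SpectralModelFit:
    """Knee-mode parameterization of one power spectrum.

    Width limits are stated as full bandwidths (2 SD), matching the
    convention of spectral-parameterization toolboxes; internally the
    Gaussian SD is bounded by half of each limit.
    """
    if fit_lo <= 0:
        raise ValueError("fit_lo must be positive (log-frequency fit)")
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    sel = (freqs >= fit_lo) & (freqs <= fit_hi)
    f = freqs[sel]
    p = power[sel]
    if np.any(p <= 0):
        raise ValueError("power must be strictly positive on the fit range")
    logp = np.log10(p)

    ap = _fit_aperiodic_robust(f, logp)
    if ap is None:
        return SpectralModelFit(np.nan, np.nan, np.nan, [], (fit_lo, fit_hi), np.nan)

    flat = logp - _aperiodic_model(ap, f)
    w_lo, w_hi = peak_width_limits[0] / 2.0, peak_width_limits[1] / 2.0
    guesses = []
    work = flat.copy()
    for _ in range(max_n_peaks):
        i = int(np.argmax(work))
        h = work[i]
        if h < peak_threshold * work.std() or h < min_peak_height:
            break
        c = f[i]
        # half-height span -> SD guess
        half = h / 2.0
        li = i
        while li > 0 and work[li] > half:
            li -= 1
        ri = i
        while ri < len(f) - 1 and work[ri] > half:
            ri += 1
        fwhm = max(f[ri] - f[li], (f[1] - f[0]) * 2)
        w = float(np.clip(fwhm / 2.355, w_lo, w_hi))
        guesses.append([c, h, w])
        work = work - h * np.exp(-((f - c) ** 2) / (2 * w**2))

    peaks = []
    if guesses:
        x0, lo_b, hi_b = [], [], []
        for c, h, w in guesses:
            x0 += [c, h, w]
            lo_b += [fit_lo, 0.0, w_lo]
            hi_b += [fit_hi, np.inf, w_hi]
        try:
            res = least_squares(
                lambda q: _gaussian_sum(q, f) - flat,
                x0=np.array(x0), bounds=(np.array(lo_b), np.array(hi_b)),
                jac=lambda q: _gaussian_sum_jac(q, f),
                max_nfev=5000,
            )
            q = res.x
        except Exception:
            q = np.array(x0)
        for i in range(0, len(q), 3):
            # a peak whose jointly-refit height falls below the minimum is
            # a noise excursion, not an oscillation; drop it
            if q[i + 1] >= min_peak_height:
                peaks.append(SpectralPeak(center=q[i], height=q[i + 1], width=q[i + 2]))
        peaks.sort(key=lambda pk: -pk.height)

    # final aperiodic refit on the peak-removed spectrum
    peak_model = _gaussian_sum(
        np.array([v for pk in peaks for v in (pk.center, pk.height, pk.width)]), f
    ) if peaks else np.zeros_like(f)
    ap2 = _fit_aperiodic(f, logp - peak_model)
    if ap2 is None:
        ap2 = ap
    fit = SpectralModelFit(
        offset=float(ap2[0]), knee=float(ap2[1]), exponent=float(ap2[2]),
        peaks=peaks, fit_range=(fit_lo, fit_hi),
    )
    pred = fit.model(f)
    ss_res = float(np.sum((logp - pred) ** 2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    fit.r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return fit


def fit_spectra(psd: PSDEstimate, **kwargs) -> list:
    """Fit the spectral model to every region of a PSDEstimate."""
    return [fit_spectral_model(psd.frequencies, row, **kwargs) for row in psd.power]


def knee_frequency_and_timescale(fit: SpectralModelFit) -> tuple:
    """Knee frequency f_k = k**(1/chi) and intrinsic timescale 1/(2 pi f_k).

    Returns ``(nan, nan)`` when the knee or exponent is non-positive
    (undefined timescale).
    """
    if not np.isfinite(fit.knee) or not np.isfinite(fit.exponent):
        return (np.nan, np.nan)
    if fit.knee <= 0 or fit.exponent <= 0:
        return (np.nan, np.nan)
    f_k = fit.knee ** (1.0 / fit.exponent)
    return (f_k, 1.0 / (2.0 * np.pi * f_k))


# ---------------------------------------------------------------------------
# oscillation scores
# ---------------------------------------------------------------------------

@dataclass
class OscillationScoreMap:
    band: str
    score: np.ndarray
    normalized_power: np.ndarray
    probability: np.ndarray


def oscillation_score(fits, bands=ADJUSTED_BANDS) -> dict:
    """Group-level oscillation score per band.

    ``fits`` is a list (participants) of lists (parcels) of
    SpectralModelFit. Per band and parcel: take each participant's
    max-power in-band peak if any; average peak power over participants
    with a detection; normalize the group map by its max over parcels;
    multiply by the detection-probability map.
    """
    if len(fits) < 1:
        raise ValueError("need at least one participant")
    n_sub = len(fits)
    n_parc = len(fits[0])
    out = {}
    for band in bands:
        power = np.full((n_sub, n_parc), np.nan)
        for s in range(n_sub):
            for r in range(n_parc):
                in_band = [
                    pk for pk in fits[s][r].peaks if band.lo <= pk.center <= band.hi
                ]
                if in_band:
                    power[s, r] = max(pk.height for pk in in_band)
        detected = np.isfinite(power)
        prob = detected.mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_power = np.nanmean(power, axis=0)
        mean_power[~np.isfinite(mean_power)] = 0.0
        if mean_power.max() > 0:
            norm = mean_power / mean_power.max()
        else:
            warnings.warn(f"no peaks detected anywhere in band {band.name}")
            norm = np.zeros(n_parc)
        out[band.name] = OscillationScoreMap(
            band=band.name, score=norm * prob, normalized_power=norm, probability=prob
        )
    return out
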