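"""Curated time-series feature catalog and feature-matrix processing.

A bank of ~100+ deterministic features spanning seven families
(distribution, autocorrelation, forecasting, fluctuation, wavelet,
entropy, spectral) computed per regional signal, standing in for
massive-feature-extraction toolboxes. Values that cannot be computed
(undefined statistics, degenerate signals) are flagged invalid rather
than raised.

Downstream processing follows the standard protocol: per-participant
normalization of each feature across parcels with an outlier-robust
sigmoid

    x_norm = 1 / (1 + exp(-(x - median) / (IQR / 1.35)))

followed by unit-interval rescaling; features that error for any
participant are pruned globally; the surviving entries are averaged into
a group parcels x features matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy import stats

from .containers import FeatureMatrix, RegionalTimeSeriesSet

__all__ = [
    "FeatureDescriptor",
    "default_catalog",
    "fast_catalog",
    "compute_feature_vector",
    "compute_feature_matrix",
    "extract_group_features",
    "acf_first_zero",
    "acf_at_lag",
    "dfa",
    "DFAResult",
    "normalize_feature_matrix",
    "robust_sigmoid",
    "aggregate_group",
    "stability_curve",
    "sample_acf",
]

DROP_INITIAL_S = 30.0   # discarded before feature extraction
ANALYZE_S = 80.0        # retained segment length


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def sample_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (1/N) sample autocorrelation, lags 0..max_lag, via FFT."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    denom = np.dot(x, x)
    if denom == 0:
        raise ValueError("constant signal has no autocorrelation")
    from scipy.fft import irfft, next_fast_len, rfft

    m = next_fast_len(2 * n)
    fx = rfft(x, m)
    acov = irfft(fx * np.conj(fx), m)[: max_lag + 1]
    return acov / denom


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def acf_first_zero(signal, fs: float, max_lag_s: float = 2.0):
    """Smallest positive lag where the sample ACF <= 0.

    Returns ``(steps, seconds)`` or ``(None, None)`` when the ACF does not
    cross within ``max_lag_s``.
    """
    max_lag = min(int(round(max_lag_s * fs)), len(signal) - 1)
    acf = sample_acf(signal, max_lag)
    below = np.flatnonzero(acf[1:] <= 0)
    if below.size == 0:
        return (None, None)
    steps = int(below[0] + 1)
    return (steps, steps / fs)


def acf_at_lag(signal, fs: float, lag_s: float) -> float:
    """Sample autocorrelation at a lag given in seconds (round-half-up)."""
    lag = _round_half_up(lag_s * fs)
    if lag < 0 or lag >= len(signal) // 2:
        raise ValueError("lag out of range")
    return float(sample_acf(signal, lag)[lag])


@dataclass
class DFAResult:
    alpha: float
    r_squared: float
    scales: np.ndarray
    fluctuations: np.ndarray
    valid: bool = True


def dfa(signal, scales=None, detrend_order: int = 1, formulation: str = "rms") -> DFAResult:
    """Detrended fluctuation analysis of the cumulative profile.

    Windows are non-overlapping; the fluctuation per scale is the RMS (or
    mean absolute, ``formulation='abs'``) of residuals from polynomial
    detrending of order ``detrend_order``; alpha is the least-squares
    slope of log F(s) vs log s.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if scales is None:
        lo = max(8, 2 * (detrend_order + 1))
        hi = n // 4
        scales = np.unique(np.geomspace(lo, hi, 18).astype(int))
    scales = np.asarray(scales, dtype=int)
    if scales.min() < 2 * (detrend_order + 1):
        raise ValueError("min scale too small for the detrend order")
    if scales.max() > n // 4:
        raise ValueError("max scale exceeds a quarter of the signal length")
    y = np.cumsum(x - x.mean())
    flucts = np.empty(scales.size)
    for i, s in enumerate(scales):
        n_win = n // s
        seg = y[: n_win * s].reshape(n_win, s)
        t = np.arange(s, dtype=float)
        V = np.vander(t, detrend_order + 1)
        # polynomial detrend of every window at once (least squares)
        coef = np.linalg.pinv(V) @ seg.T
        resid = seg - (V @ coef).T
        if formulation == "rms":
            flucts[i] = np.sqrt(np.mean(resid**2))
        elif formulation == "abs":
            flucts[i] = np.mean(np.abs(resid))
        else:
            raise ValueError(f"unknown formulation {formulation!r}")
    # fluctuations at rounding level mean the profile was detrended exactly
    floor = 1e-10 * max(1.0, float(np.sqrt(np.mean(y**2))))
    if np.any(flucts <= floor):
        return DFAResult(np.nan, np.nan, scales, flucts, valid=False)
    logs, logf = np.log(scales), np.log(flucts)
    slope, intercept = np.polyfit(logs, logf, 1)
    pred = slope * logs + intercept
    ss_tot = np.sum((logf - logf.mean()) ** 2)
    r2 = 1.0 - np.sum((logf - pred) ** 2) / ss_tot if ss_tot > 0 else np.nan
    span_ok = scales.size >= 4 and scales.max() / scales.min() >= 10
    return DFAResult(float(slope), float(r2), scales, flucts, valid=bool(span_ok))


def rolling_linear_forecast_residuals(x: np.ndarray, window: int) -> np.ndarray:
    """One-step-ahead residuals of a rolling linear (trend) forecaster.

    A line is fit to each ``window``-sample stretch and extrapolated one
    step; vectorized via the closed-form OLS slope.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= window:
        raise ValueError("signal shorter than forecast window")
    W = np.lib.stride_tricks.sliding_window_view(x, window)[:-1]
    t = np.arange(window, dtype=float)
    tbar = t.mean()
    stt = np.sum((t - tbar) ** 2)
    xbar = W.mean(axis=1)
    slope = (W @ (t - tbar)) / stt
    pred = xbar + slope * (window - tbar)
    return x[window:] - pred


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy of ordinal patterns."""
    x = np.asarray(x, dtype=float)
    n = x.size - (order - 1) * delay
    if n < 10:
        raise ValueError("signal too short for permutation entropy")
    emb = np.lib.stride_tricks.sliding_window_view(x, (order - 1) * delay + 1)[:, ::delay]
    codes = np.argsort(np.argsort(emb, axis=1), axis=1)
    base = order ** np.arange(order)
    keys = codes @ base
    _, counts = np.unique(keys, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(math.factorial(order)))


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    family: str
    func: callable = field(compare=False)
    params: tuple = ()


class _SignalContext:
    """Caches shared intermediates (z-scored signal, ACF, PSD) per signal."""

    def __init__(self, x: np.ndarray, fs: float):
        self.x = np.asarray(x, dtype=float)
        self.fs = fs
        self.n = self.x.size
        self._cache = {}

    @property
    def mean(self):
        return self._get("mean", lambda: float(self.x.mean()))

    @property
    def std(self):
        return self._get("std", lambda: float(self.x.std()))

    @property
    def z(self):
        def make():
            if self.std == 0:
                raise ValueError("constant signal")
            return (self.x - self.mean) / self.std
        return self._get("z", make)

    @property
    def acf(self):
        return self._get("acf", lambda: sample_acf(self.x, min(2000, self.n - 1)))

    @property
    def psd(self):
        def make():
            win = min(4.0, self.n / self.fs / 2.0)
            nperseg = int(round(win * self.fs))
            return sps.welch(self.x, fs=self.fs, window="hann", nperseg=nperseg,
                             noverlap=nperseg // 2)
        return self._get("psd", make)

    @property
    def wavelet(self):
        return self._get("wavelet", lambda: pywt.wavedec(self.z, "db4", level=6))

    def _get(self, key, make):
        if key not in self._cache:
            self._cache[key] = make()
        return self._cache[key]


def _acf_lag_steps(lag):
    return lambda c: float(c.acf[lag]) if lag < c.acf.size else np.nan


def _acf_lag_ms(ms):
    def f(c):
        lag = _round_half_up(ms / 1000.0 * c.fs)
        return float(c.acf[lag]) if 0 < lag < c.acf.size else np.nan
    return f


def _band_rel_power(lo, hi):
    def f(c):
        fr, p = c.psd
        tot = np.trapezoid(p, fr)
        sel = (fr >= lo) & (fr <= hi)
        if tot == 0 or not sel.any():
            raise ValueError("empty band")
        return float(np.trapezoid(p[sel], fr[sel]) / tot)
    return f


def _quantile(q):
    return lambda c: float(np.quantile(c.z, q))


def _dfa_feature(order, formulation, attr="alpha"):
    def f(c):
        key = ("dfa", order, formulation)
        r = c._get(key, lambda: dfa(c.x, detrend_order=order, formulation=formulation))
        if not r.valid or not np.isfinite(r.alpha):
            raise ValueError("DFA undefined")
        return float(getattr(r, attr))
    return f


def _forecast_feature(window, kind):
    def f(c):
        res = rolling_linear_forecast_residuals(c.z, window)
        if kind == "var":
            return float(res.var())
        return float(np.mean(np.abs(res)))
    return f


def _wavelet_rel_energy(level):
    def f(c):
        coeffs = c.wavelet
        energies = np.array([np.sum(ci**2) for ci in coeffs])
        tot = energies.sum()
        if tot == 0:
            raise ValueError("zero-energy signal")
        return float(energies[level] / tot)
    return f


def _spectral_centroid(c):
    fr, p = c.psd
    tot = p.sum()
    if tot == 0:
        raise ValueError("empty spectrum")
    return float((fr * p).sum() / tot)


def _spectral_edge(frac):
    def f(c):
        fr, p = c.psd
        cum = np.cumsum(p)
        if cum[-1] == 0:
            raise ValueError("empty spectrum")
        return float(fr[np.searchsorted(cum, frac * cum[-1])])
    return f


def _spectral_flatness(c):
    fr, p = c.psd
    p = p[1:]
    if np.any(p <= 0):
        p = p + 1e-30
    return float(np.exp(np.mean(np.log(p))) / np.mean(p))


def _spectral_entropy(c):
    fr, p = c.psd
    q = p / p.sum()
    q = q[q > 0]
    return float(-(q * np.log(q)).sum() / np.log(len(p)))


def _loglog_slope(lo, hi):
    def f(c):
        fr, p = c.psd
        sel = (fr >= lo) & (fr <= hi) & (p > 0)
        if sel.sum() < 4:
            raise ValueError("too few bins for slope")
        return float(np.polyfit(np.log10(fr[sel]), np.log10(p[sel]), 1)[0])
    return f


def _hist_entropy(bins):
    def f(c):
        counts, _ = np.histogram(c.z, bins=bins)
        p = counts / counts.sum()
        p = p[p > 0]
        return float(-(p * np.log(p)).sum() / np.log(bins))
    return f


def _acf_sum(n_lags):
    return lambda c: float(c.acf[1 : n_lags + 1].sum())


def _first_zero_steps(c):
    steps, _ = acf_first_zero(c.x, c.fs, max_lag_s=min(2.0, (c.n - 1) / c.fs))
    if steps is None:
        raise ValueError("ACF does not cross zero")
    return float(steps)


def _first_1oe_steps(c):
    target = 1.0 / np.e
    below = np.flatnonzero(c.acf[1:] <= target)
    if below.size == 0:
        raise ValueError("ACF does not decay below 1/e")
    return float(below[0] + 1)


def _ar_resid_var(p_order):
    def f(c):
        # Yule-Walker AR(p) one-step residual variance, relative to var(x)
        r = c.acf[: p_order + 1]
        R = np.array([[r[abs(i - j)] for j in range(p_order)] for i in range(p_order)])
        coeffs = np.linalg.solve(R, r[1 : p_order + 1])
        return float(1.0 - coeffs @ r[1 : p_order + 1])
    return f


def _pacf_at(lag):
    def f(c):
        from statsmodels.tsa.stattools import pacf
        # computed from the first few thousand samples for speed
        seg = c.x[: min(c.n, 20000)]
        vals = pacf(seg, nlags=lag, method="yw")
        return float(vals[lag])
    return f


def _outlier_frac(thresh):
    return lambda c: float(np.mean(np.abs(c.z) > thresh))


def _trimmed_mean_shift(c):
    return float(stats.trim_mean(c.z, 0.1))


def _perm_entropy(order):
    return lambda c: permutation_entropy(c.z, order=order)


def default_catalog() -> list:
    """The standard catalog (~110 features over seven families)."""
    cat: list = []

    def add(name, family, func):
        cat.append(FeatureDescriptor(name, family, func))

    # distribution -----------------------------------------------------
    add("dist_mean", "distribution", lambda c: c.mean)
    add("dist_std", "distribution", lambda c: c.std)
    add("dist_skewness", "distribution", lambda c: float(stats.skew(c.x)))
    add("dist_kurtosis", "distribution", lambda c: float(stats.kurtosis(c.x)))
    add("dist_median_z", "distribution", lambda c: float(np.median(c.z)))
    add("dist_iqr_over_std", "distribution",
        lambda c: float(stats.iqr(c.z)))
    add("dist_mad", "distribution",
        lambda c: float(np.median(np.abs(c.z - np.median(c.z)))))
    for q in (0.01, 0.05, 0.25, 0.75, 0.95, 0.99):
        add(f"dist_q{int(q*100):02d}", "distribution", _quantile(q))
    for t in (1.0, 2.0, 3.0):
        add(f"dist_outlier_gt{t:.0f}sd", "distribution", _outlier_frac(t))
    add("dist_trimmed_mean", "distribution", _trimmed_mean_shift)
    add("dist_range_over_std", "distribution",
        lambda c: float(c.z.max() - c.z.min()))
    add("dist_abs_mean", "distribution", lambda c: float(np.mean(np.abs(c.z))))
    add("dist_sign_balance", "distribution",
        lambda c: float(np.mean(c.z > 0)))

    # autocorrelation --------------------------------------------------
    for lag in (1, 2, 3, 4, 5, 6, 8, 10, 12, 15, 20, 24, 32, 40, 50, 64,
                75, 100, 128, 150, 200, 300):
        add(f"acf_lag{lag:03d}", "autocorrelation", _acf_lag_steps(lag))
    def _envelope_acf(lag):
        def f(c):
            env = np.abs(c.z)
            return float(sample_acf(env, lag)[lag])
        return f
    for lag in (1, 10, 24):
        add(f"acf_envelope_lag{lag:03d}", "autocorrelation", _envelope_acf(lag))
    def _hjorth_mobility(c):
        return float(np.std(np.diff(c.z)))
    def _hjorth_complexity(c):
        d1 = np.diff(c.z)
        d2 = np.diff(d1)
        m1 = np.std(d1)
        if m1 == 0 or np.std(d2) == 0:
            raise ValueError("flat derivative")
        return float((np.std(d2) / m1) / m1)
    add("acf_hjorth_mobility", "autocorrelation", _hjorth_mobility)
    add("acf_hjorth_complexity", "autocorrelation", _hjorth_complexity)
    add("acf_zero_cross_rate", "autocorrelation",
        lambda c: float(np.mean(np.diff(np.signbit(c.z)) != 0)))
    for ms in (10, 20, 48, 100, 200):
        add(f"acf_{ms}ms", "autocorrelation", _acf_lag_ms(ms))
    add("acf_first_zero", "autocorrelation", _first_zero_steps)
    add("acf_first_1oe", "autocorrelation", _first_1oe_steps)
    for n_lags in (10, 20, 50):
        add(f"acf_sum{n_lags}", "autocorrelation", _acf_sum(n_lags))
    for lag in (1, 2, 3):
        add(f"pacf_lag{lag}", "autocorrelation", _pacf_at(lag))

    # forecasting ------------------------------------------------------
    for w in (5, 10, 25, 50):
        add(f"fc_lin{w}_resid_var", "forecasting", _forecast_feature(w, "var"))
        add(f"fc_lin{w}_resid_absmean", "forecasting", _forecast_feature(w, "abs"))
    for p_ord in (1, 2, 5):
        add(f"fc_ar{p_ord}_resid_var", "forecasting", _ar_resid_var(p_ord))

    # fluctuation ------------------------------------------------------
    add("dfa_alpha", "fluctuation", _dfa_feature(1, "rms"))
    add("dfa_alpha_order2", "fluctuation", _dfa_feature(2, "rms"))
    add("dfa_alpha_absfluct", "fluctuation", _dfa_feature(1, "abs"))
    add("dfa_r_squared", "fluctuation", _dfa_feature(1, "rms", attr="r_squared"))

    # wavelet ----------------------------------------------------------
    for lvl in range(7):
        add(f"wav_rel_energy_l{lvl}", "wavelet", _wavelet_rel_energy(lvl))
    def _wav_entropy(c):
        energies = np.array([np.sum(ci**2) for ci in c.wavelet])
        p = energies / energies.sum()
        p = p[p > 0]
        return float(-(p * np.log(p)).sum() / np.log(len(energies)))
    add("wav_entropy", "wavelet", _wav_entropy)

    # entropy ----------------------------------------------------------
    add("ent_hist10", "entropy", _hist_entropy(10))
    add("ent_hist25", "entropy", _hist_entropy(25))
    add("ent_perm3", "entropy", _perm_entropy(3))
    add("ent_perm5", "entropy", _perm_entropy(5))
    add("ent_spectral", "entropy", _spectral_entropy)

    # spectral ---------------------------------------------------------
    for name, lo, hi in (
        ("delta", 2, 4), ("theta", 5, 7), ("alpha", 8, 12),
        ("beta", 15, 29), ("lo_gamma", 30, 59), ("hi_gamma", 60, 90),
    ):
        add(f"spec_rel_{name}", "spectral", _band_rel_power(lo, hi))
    add("spec_centroid", "spectral", _spectral_centroid)
    add("spec_edge90", "spectral", _spectral_edge(0.90))
    add("spec_edge95", "spectral", _spectral_edge(0.95))
    add("spec_flatness", "spectral", _spectral_flatness)
    add("spec_loglog_slope_2_40", "spectral", _loglog_slope(2, 40))
    add("spec_loglog_slope_30_90", "spectral", _loglog_slope(30, 90))

    names = [d.name for d in cat]
    assert len(names) == len(set(names)), "duplicate feature names in catalog"
    return cat


def fast_catalog() -> list:
    """Small fast subset (catch22-analogue) for the stability analysis."""
    keep = {
        "dist_skewness", "dist_kurtosis", "dist_q05", "dist_q95",
        "dist_outlier_gt2sd", "dist_mad",
        "acf_lag001", "acf_lag003", "acf_lag010", "acf_lag024",
        "acf_first_zero", "acf_first_1oe", "acf_sum20",
        "fc_lin5_resid_var", "fc_ar1_resid_var", "fc_ar2_resid_var",
        "dfa_alpha", "wav_entropy",
        "ent_hist10", "ent_perm3", "ent_spectral",
        "spec_centroid",
    }
    return [d for d in default_catalog() if d.name in keep]


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def compute_feature_vector(signal, fs: float, catalog=None):
    """Evaluate the catalog on one signal; failures become invalid flags."""
    x = np.asarray(signal, dtype=float)
    if x.size < 256:
        raise ValueError("signal too short (need >= 256 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if catalog is None:
        catalog = default_catalog()
    ctx = _SignalContext(x, fs)
    values = np.full(len(catalog), np.nan)
    valid = np.zeros(len(catalog), dtype=bool)
    for i, desc in enumerate(catalog):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = desc.func(ctx)
            if np.isfinite(v):
                values[i] = v
                valid[i] = True
        except Exception:
            pass
    return values, valid


def compute_feature_matrix(
    ts: RegionalTimeSeriesSet,
    participant: int = 0,
    catalog=None,
    parcel_ids=None,
    drop_initial_s: float = DROP_INITIAL_S,
    analyze_s: float = ANALYZE_S,
) -> FeatureMatrix:
    """Features for every region of one participant.

    The first ``drop_initial_s`` seconds are discarded and the following
    ``analyze_s`` seconds retained (truncated to what is available).
    """
    if catalog is None:
        catalog = default_catalog()
    i0 = int(round(drop_initial_s * ts.fs))
    i1 = i0 + int(round(analyze_s * ts.fs))
    if i0 >= ts.n_samples:
        i0 = 0
    i1 = min(i1, ts.n_samples)
    names = [d.name for d in catalog]
    vals = np.empty((ts.n_regions, len(catalog)))
    mask = np.empty((ts.n_regions, len(catalog)), dtype=bool)
    for r in range(ts.n_regions):
        vals[r], mask[r] = compute_feature_vector(
            ts.data[participant, r, i0:i1], ts.fs, catalog
        )
    if parcel_ids is None:
        parcel_ids = [f"parcel_{r:03d}" for r in range(ts.n_regions)]
    values = pd.DataFrame(vals, index=parcel_ids, columns=names)
    return FeatureMatrix(
        values, pd.DataFrame(mask, index=parcel_ids, columns=names),
        normalization="raw", participant=ts.participant_ids[participant],
    )


# ---------------------------------------------------------------------------
# normalization / aggregation
# ---------------------------------------------------------------------------

def robust_sigmoid(x: np.ndarray, iqr_norm: float = 1.35):
    """Outlier-robust sigmoid then unit rescale of a 1-D vector.

    ``iqr_norm`` divides the IQR (1.35 makes the sigmoid slope match a
    unit-SD Gaussian; 1.0 uses the bare IQR). Returns ``(scaled, valid)``;
    invalid (all-NaN) when the IQR is zero.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    iqr = np.quantile(x, 0.75) - np.quantile(x, 0.25)
    if iqr == 0:
        return np.full_like(x, np.nan), False
    with np.errstate(over="ignore"):  # saturates cleanly for extreme outliers
        norm = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / iqr_norm)))
    lo, hi = norm.min(), norm.max()
    if hi == lo:
        return np.full_like(x, np.nan), False
    return (norm - lo) / (hi - lo), True


def normalize_feature_matrix(fm: FeatureMatrix, iqr_norm: float = 1.35) -> FeatureMatrix:
    """Sigmoid-normalize each feature across parcels (valid entries only)."""
    values = fm.values.to_numpy(dtype=float).copy()
    mask = fm.mask.to_numpy(dtype=bool).copy()
    for j in range(values.shape[1]):
        valid = mask[:, j]
        if valid.sum() < 3:
            mask[:, j] = False
            values[:, j] = np.nan
            continue
        scaled, ok = robust_sigmoid(values[valid, j], iqr_norm=iqr_norm)
        if not ok:
            mask[:, j] = False
            values[:, j] = np.nan
            continue
        col = np.full(values.shape[0], np.nan)
        col[valid] = scaled
        values[:, j] = col
        mask[:, j] = valid
    return FeatureMatrix(
        pd.DataFrame(values, index=fm.values.index, columns=fm.values.columns),
        pd.DataFrame(mask, index=fm.values.index, columns=fm.values.columns),
        normalization="sigmoid-scaled",
        participant=fm.participant,
    )


def aggregate_group(matrices: list) -> FeatureMatrix:
    """Drop features invalid in any participant; average the rest."""
    if not matrices:
        raise ValueError("no matrices to aggregate")
    cols = matrices[0].feature_names
    index = matrices[0].values.index
    for fm in matrices[1:]:
        if fm.feature_names != cols or not fm.values.index.equals(index):
            raise ValueError("matrices must share catalog and parcellation")
    keep = np.ones(len(cols), dtype=bool)
    for fm in matrices:
        keep &= fm.mask.to_numpy(dtype=bool).all(axis=0)
    kept_cols = [c for c, k in zip(cols, keep) if k]
    if not kept_cols:
        raise RuntimeError("no feature valid in every participant")
    stack = np.stack([fm.values[kept_cols].to_numpy(dtype=float) for fm in matrices])
    mean = stack.mean(axis=0)
    values = pd.DataFrame(mean, index=index, columns=kept_cols)
    return FeatureMatrix(values, normalization=matrices[0].normalization,
                         participant="group")


def extract_group_features(
    ts: RegionalTimeSeriesSet, catalog=None, parcel_ids=None,
    iqr_norm: float = 1.35, **kwargs,
):
    """Per-participant extraction + normalization + group averaging."""
    per_sub = []
    for s in range(ts.n_participants):
        fm = compute_feature_matrix(ts, participant=s, catalog=catalog,
                                    parcel_ids=parcel_ids, **kwargs)
        per_sub.append(normalize_feature_matrix(fm, iqr_norm=iqr_norm))
    return aggregate_group(per_sub), per_sub


# ---------------------------------------------------------------------------
# segment-length stability
# ---------------------------------------------------------------------------

def stability_curve(signal, fs: float, lengths_s=None, catalog=None):
    """Pearson r between feature vectors of consecutive segment lengths.

    Segments are nested from the start of the recording. Returns a
    DataFrame with columns (length_s, r) where r compares the features of
    each length against the previous one (NaN where undefined).
    """
    if lengths_s is None:
        lengths_s = np.arange(5, 130, 5)
    if catalog is None:
        catalog = fast_catalog()
    x = np.asarray(signal, dtype=float)
    avail = x.size / fs
    lengths_s = np.asarray([L for L in lengths_s if L <= avail], dtype=float)
    if lengths_s.size < 2:
        raise ValueError("need at least two evaluable segment lengths")
    if lengths_s.size < 25 and avail < 125:
        warnings.warn("signal shorter than 125 s; stability curve truncated")
    vecs = []
    for L in lengths_s:
        seg = x[: int(round(L * fs))]
        vals, valid = compute_feature_vector(seg, fs, catalog)
        vecs.append((vals, valid))
    rows = []
    for i in range(1, len(vecs)):
        v0, m0 = vecs[i - 1]
        v1, m1 = vecs[i]
        common = m0 & m1
        if common.sum() < 3:
            rows.append((lengths_s[i], np.nan))
            continue
        a, b = v0[common], v1[common]
        if a.std() == 0 or b.std() == 0:
            rows.append((lengths_s[i], np.nan))
            continue
        rows.append((lengths_s[i], float(np.corrcoef(a, b)[0, 1])))
    return pd.DataFrame(rows, columns=["length_s", "r"])
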