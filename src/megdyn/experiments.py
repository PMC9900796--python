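"""Benchmark experiments: parameter recovery and statistical calibration.

These are the package's standing validation studies, reused by the test
suite, the acceptance script, and the analysis drivers. Every experiment
is a pure function of its seed; sizes default to the study conditions
(100 parcels, 80 s at 509 Hz, 1 000 spins) scaled to run on one CPU in
minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from . import synthgen as sg
from ._rng import split_rng
from .plsmap import pls_bootstrap_loadings, pls_fit, pls_permutation_test
from .spatialnulls import make_spin_ensemble, spin_pvalue
from .spectral import fit_spectral_model, knee_frequency_and_timescale, welch_psd
from .tsfeat import dfa, sample_acf

__all__ = [
    "timescale_recovery",
    "dfa_scaling_check",
    "ar1_acf_check",
    "pls_weight_recovery",
    "spin_type1_calibration",
    "pls_null_calibration",
    "bootstrap_coverage",
]

CALIBRATION_LENGTHSCALE = 0.5  # rad on the projection sphere


def timescale_recovery(seed: int, n_participants: int = 6,
                       n_per_hemisphere: int = 50) -> dict:
    """Recover tau from generated 80 s / 509 Hz cohorts with a knee gradient.

    Fits every participant's Welch spectrum per region and takes the
    cohort median tau map; reports relative errors against the generating
    knee parameters, plus the noiseless closed-form recovery of (k, chi).
    """
    g = sg.gen_parcellation(n_per_hemisphere, seed=seed)
    n = g.n_parcels
    latent = np.linspace(-1.0, 1.0, n)
    profile = sg.AperiodicProfile(offset=0.0, knee=150.0, exponent=2.0,
                                  knee_slope=100.0)
    ts = sg.gen_regional_timeseries(
        g, 80.0, 509.0, aperiodic_profile=profile, seed=seed,
        latent_map=latent, n_participants=n_participants,
    )
    _, k, chi = profile.per_region(latent)
    true_tau = 1.0 / (2.0 * np.pi * k ** (1.0 / chi))
    taus = np.full((n_participants, n), np.nan)
    for s in range(n_participants):
        psd = welch_psd(ts, participant=s)
        for r in range(n):
            fit = fit_spectral_model(psd.frequencies, psd.power[r])
            taus[s, r] = knee_frequency_and_timescale(fit)[1]
    tau_map = np.nanmedian(taus, axis=0)
    rel_err = np.abs(tau_map - true_tau) / true_tau

    # noiseless closed-form spectra: (k, chi) recovery of the fit itself
    f = np.arange(1.0, 60.25, 0.25)
    noiseless = fit_spectral_model(f, 10.0 ** (0.0 - np.log10(100.0 + f**2)))
    return {
        "tau_median_rel_err": float(np.median(rel_err)),
        "tau_p90_rel_err": float(np.percentile(rel_err, 90)),
        "noiseless_knee_rel_err": abs(noiseless.knee - 100.0) / 100.0,
        "noiseless_exponent_rel_err": abs(noiseless.exponent - 2.0) / 2.0,
        "n": n,
    }


def dfa_scaling_check(seed: int, n_runs: int = 20, n_samples: int = 40000) -> dict:
    """Median DFA exponent of white noise (0.5) and its cumulative sum (1.5)."""
    wn, br = [], []
    for i in range(n_runs):
        x = split_rng(seed, "dfa", i).standard_normal(n_samples)
        wn.append(dfa(x).alpha)
        br.append(dfa(np.cumsum(x)).alpha)
    return {"white_alpha": float(np.median(wn)),
            "brownian_alpha": float(np.median(br)), "n": n_samples}


def ar1_acf_check(seed: int, coeff: float = 0.9, lag: int = 24,
                  n_samples: int = 40000) -> dict:
    """Sample ACF of an AR(1) process at a long lag vs theory coeff**lag."""
    eps = split_rng(seed, "ar1").standard_normal(n_samples)
    x = sps.lfilter([1.0], [1.0, -coeff], eps)
    got = float(sample_acf(x, lag)[lag])
    return {"acf": got, "theory": coeff**lag, "abs_err": abs(got - coeff**lag),
            "n": n_samples}


def pls_weight_recovery(seed: int, n_replicates: int = 50,
                        coupling: float = 0.9, noise_sd: float = 0.5) -> dict:
    """|corr| between LV1 weights and generating weights across replicates."""
    g = sg.gen_parcellation(50, seed=seed)
    rs = []
    for rep in range(n_replicates):
        X, Y, truth = sg.gen_coupled_feature_sets(
            g, 10, 6, coupling, noise_sd, seed=seed * 1000 + rep
        )
        fit = pls_fit(X, Y)
        rs.append(abs(np.corrcoef(fit.U[:, 0], truth.ts_weights)[0, 1]))
    return {"median_abs_r": float(np.median(rs)), "min_abs_r": float(np.min(rs)),
            "n": g.n_parcels}


def spin_type1_calibration(seed: int, n_replicates: int = 500,
                           n_perms: int = 1000, alpha: float = 0.05) -> dict:
    """Spin-test false-positive rate on independent smooth map pairs."""
    g = sg.gen_parcellation(50, seed=seed)
    ens = make_spin_ensemble(g, n_perms=n_perms, seed=seed)
    ps = np.empty(n_replicates)
    for rep in range(n_replicates):
        a = sg.gen_smooth_map(g, CALIBRATION_LENGTHSCALE, seed=seed * 1000 + rep,
                              stream="cal_a")
        b = sg.gen_smooth_map(g, CALIBRATION_LENGTHSCALE, seed=seed * 1000 + rep,
                              stream="cal_b")
        _, ps[rep] = spin_pvalue(a, b, ens)
    return {
        "type1_rate": float((ps < alpha).mean()),
        "ks_uniform": float(stats.kstest(ps, "uniform").statistic),
        "n": n_replicates,
    }


def pls_null_calibration(seed: int, n_replicates: int = 200,
                         n_perms: int = 500) -> dict:
    """Uniformity of the LV1 permutation p-value under zero coupling."""
    g = sg.gen_parcellation(50, seed=seed)
    ens = make_spin_ensemble(g, n_perms=n_perms, seed=seed)
    ps = np.empty(n_replicates)
    for rep in range(n_replicates):
        X, Y, _ = sg.gen_coupled_feature_sets(g, 8, 5, 0.0, 1.0,
                                              seed=seed * 1000 + rep)
        ps[rep] = pls_permutation_test(X, Y, ens)[0]
    return {"ks_uniform": float(stats.kstest(ps, "uniform").statistic),
            "mean_p": float(ps.mean()), "n": n_replicates}


def bootstrap_coverage(seed: int, n_replicates: int = 200, n_boot: int = 500,
                       loading: float = 0.8, t: int = 20, m: int = 10,
                       n: int = 100) -> dict:
    """Coverage of 95% bootstrap CIs for a known population loading.

    All columns carry the latent with weight ``loading``; the population
    LV1 loading of a column on the (equal-weight) score follows in closed
    form from the exchangeable correlation structure.
    """
    rho = loading**2
    true_loading = (1 + (t - 1) * rho) / np.sqrt(t + t * (t - 1) * rho)
    covered = 0
    for rep in range(n_replicates):
        rng = split_rng(seed, "coverage", rep)
        z = rng.standard_normal(n)
        X = loading * z[:, None] + np.sqrt(1 - rho) * rng.standard_normal((n, t))
        Y = loading * z[:, None] + np.sqrt(1 - rho) * rng.standard_normal((n, m))
        Xdf, Ydf = pd.DataFrame(X), pd.DataFrame(Y)
        fit = pls_fit(Xdf, Ydf)
        # orient the (sign-arbitrary) LV toward the known-positive truth
        sign = 1.0 if fit.x_loadings[:, 0].sum() >= 0 else -1.0
        x_ci, _ = pls_bootstrap_loadings(Xdf, Ydf, n_boot=n_boot, seed=seed + rep)
        lo, hi = sorted((sign * x_ci[0][0, 0], sign * x_ci[1][0, 0]))
        if lo <= true_loading <= hi:
            covered += 1
    return {"coverage": covered / n_replicates, "true_loading": float(true_loading),
            "n": n_replicates}
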