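"""Signal-to-noise controls and empty-room noise comparison.

Source-level SNR follows the standard forward-model expression

    SNR = 10 log10( (a^2 / N) * sum_k  b_k^2 / s_k^2 )     [dB]

with source amplitude a (default 10 nAm, a typical dipole strength),
sensor gains b_k and sensor noise variances s_k^2. Features correlated
with the SNR map can either be removed (uncorrected spin p < 0.05 — a
deliberately conservative removal rule, since correction would remove
fewer features) or the SNR map regressed out of every feature column.
The empty-room pathway compares PCA structure of noise-recording features
to resting-state features after Procrustes alignment of the weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureMatrix
from .gradients import fit_pca, procrustes_align, zscore_columns
from .spatialnulls import SpinEnsemble, fdr_bh, spin_pvalue

__all__ = [
    "SensorModel",
    "snr_db",
    "snr_feature_filter",
    "regress_covariate",
    "noise_component_comparison",
]

DEFAULT_DIPOLE_NAM = 10.0  # typical dipole strength, nAm


@dataclass
class SensorModel:
    """Per-source forward model: gains and noise variances over N sensors."""

    gains: np.ndarray          # b_k, signal per unit source amplitude
    noise_var: np.ndarray      # s_k^2
    amplitude: float = DEFAULT_DIPOLE_NAM  # a, nAm

    def __post_init__(self):
        self.gains = np.atleast_1d(np.asarray(self.gains, dtype=float))
        self.noise_var = np.atleast_1d(np.asarray(self.noise_var, dtype=float))
        if self.gains.size != self.noise_var.size or self.gains.size < 1:
            raise ValueError("gains and noise_var must be same nonzero length")

    @property
    def n_sensors(self) -> int:
        return self.gains.size


def snr_db(model: SensorModel) -> float:
    """SNR in dB: 10 log10( (a^2/N) sum_k b_k^2 / s_k^2 )."""
    if np.any(model.noise_var <= 0):
        raise ValueError("noise variances must be positive")
    ratio = (model.amplitude**2 / model.n_sensors) * np.sum(
        model.gains**2 / model.noise_var
    )
    return float(10.0 * np.log10(ratio))


def snr_feature_filter(
    features: FeatureMatrix, snr_map, ensemble: SpinEnsemble,
    alpha: float = 0.05, use_fdr: bool = False,
):
    """Remove features whose Pearson correlation with SNR is spin-significant.

    By default p < alpha uncorrected removes the feature (the conservative
    rule: more features are removed than under FDR); ``use_fdr=True``
    switches to BH-corrected removal. Returns ``(retained FeatureMatrix,
    report DataFrame)``.
    """
    snr = np.asarray(snr_map, dtype=float)
    if np.ptp(snr) == 0:
        raise ValueError("constant SNR map: correlation undefined")
    if snr.size != features.n_parcels:
        raise ValueError("SNR map does not match the parcellation")
    rows = []
    for name in features.feature_names:
        col = features.values[name].to_numpy(dtype=float)
        if np.ptp(col[np.isfinite(col)]) == 0 or not np.all(np.isfinite(col)):
            rows.append((name, np.nan, np.nan))
            continue
        r, p = spin_pvalue(col, snr, ensemble, statistic="pearson")
        rows.append((name, r, p))
    report = pd.DataFrame(rows, columns=["feature", "r", "p_spin"]).set_index("feature")
    p = report["p_spin"].to_numpy()
    if use_fdr:
        ok = np.isfinite(p)
        removed = np.zeros(len(report), dtype=bool)
        if ok.any():
            removed[ok], _ = fdr_bh(p[ok], q=alpha)
    else:
        removed = np.where(np.isfinite(p), p < alpha, False)
    report["removed"] = removed
    keep = [n for n, rm in zip(report.index, removed) if not rm]
    if not keep:
        raise RuntimeError(
            "SNR filter removed every feature; the feature set is confound-dominated"
        )
    retained = FeatureMatrix(
        features.values[keep].copy(), features.mask[keep].copy(),
        features.normalization, features.participant,
    )
    return retained, report


def regress_covariate(features: FeatureMatrix, covariate_map) -> FeatureMatrix:
    """OLS-residualize every feature column on intercept + covariate."""
    cov = np.asarray(covariate_map, dtype=float)
    if np.ptp(cov) == 0:
        raise ValueError("constant covariate")
    n = features.n_parcels
    if n < 3:
        raise ValueError("need at least 3 parcels")
    if cov.size != n:
        raise ValueError("covariate does not match the parcellation")
    design = np.column_stack([np.ones(n), cov])
    V = features.values.to_numpy(dtype=float)
    M = features.mask.to_numpy(dtype=bool)
    out = np.full_like(V, np.nan)
    for j in range(V.shape[1]):
        valid = M[:, j]
        if valid.sum() < 3:
            continue
        beta, *_ = np.linalg.lstsq(design[valid], V[valid, j], rcond=None)
        out[valid, j] = V[valid, j] - design[valid] @ beta
    return FeatureMatrix(
        pd.DataFrame(out, index=features.values.index, columns=features.values.columns),
        features.mask.copy(), "raw", features.participant,
    )


def noise_component_comparison(
    rest_features: FeatureMatrix, noise_features: FeatureMatrix,
    ensemble: SpinEnsemble,
):
    """Correlate rest PC1 with the Procrustes-aligned noise PC1 map.

    Both matrices are reduced to their common valid feature set, PCA is
    fitted to each, noise weights are aligned to rest weights by
    orthogonal Procrustes, and the resulting first component score maps
    are compared with a spin test. Returns ``(r_s, p_spin, details)``.
    """
    common = [
        c for c in rest_features.feature_names
        if c in set(noise_features.feature_names)
        and rest_features.mask[c].all() and noise_features.mask[c].all()
        and rest_features.values[c].std() > 0 and noise_features.values[c].std() > 0
    ]
    if len(common) < 10:
        raise ValueError("fewer than 10 shared valid features")
    rest_df = rest_features.values[common]
    noise_df = noise_features.values[common]
    rest_pca = fit_pca(rest_df)
    noise_pca = fit_pca(noise_df)
    k = min(rest_pca.n_components, noise_pca.n_components)
    aligned, R = procrustes_align(rest_pca.weights[:, :k], noise_pca.weights[:, :k])
    noise_scores = zscore_columns(noise_df.to_numpy(dtype=float)) @ aligned
    r, p = spin_pvalue(rest_pca.score_map(1), noise_scores[:, 0], ensemble,
                       statistic="spearman")
    details = {
        "rest_pc1": rest_pca.score_map(1),
        "noise_pc1_aligned": noise_scores[:, 0],
        "rotation": R,
        "n_common_features": len(common),
    }
    return r, p, details
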