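"""Dominant spatial gradients of the feature matrix.

The gradient is the first principal component of the column-standardized
group parcels x features matrix: its scores form a brain map, its
loadings (correlation of each feature with the score map) describe the
feature composition, and spin tests assess both loadings and map-to-map
comparisons. Procrustes alignment relates component weights across
datasets (e.g., resting vs empty-room recordings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orthogonal_procrustes

from .containers import FeatureMatrix
from .spatialnulls import SpinEnsemble, fdr_bh, spin_pvalue

__all__ = [
    "PCAResult",
    "fit_pca",
    "component_loadings",
    "correlate_maps",
    "correlate_map_family",
    "procrustes_align",
    "zscore_columns",
]


def zscore_columns(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be z-scored")
    return (X - mu) / sd


@dataclass
class PCAResult:
    scores: np.ndarray              # (n_parcels, n_components)
    weights: np.ndarray             # (n_features, n_components), orthonormal
    variance_explained: np.ndarray  # fractions summing to 1
    feature_names: list
    parcel_ids: list

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def score_map(self, component: int = 1) -> np.ndarray:
        return self.scores[:, component - 1]


def fit_pca(matrix, reference_map=None) -> PCAResult:
    """PCA of the column-standardized feature matrix.

    ``matrix`` is a FeatureMatrix (all-valid entries required: aggregate
    first) or a parcels x features DataFrame. All ``min(n-1, p)``
    components are kept so variance fractions sum to 1. Each component's
    sign is fixed so its scores correlate nonnegatively (Spearman) with
    ``reference_map`` (default: the first feature column).
    """
    if isinstance(matrix, FeatureMatrix):
        if not matrix.mask.to_numpy(dtype=bool).all():
            raise ValueError("feature matrix contains invalid entries; aggregate first")
        df = matrix.values
    else:
        df = matrix
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 parcels and 2 features")
    Z = zscore_columns(X)
    # SVD of the centered standardized matrix: right singular vectors are
    # the component weights, singular values give the eigen-spectrum
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    if not np.any(s > 0):
        raise ValueError("rank-0 matrix")
    k = min(n - 1, p)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    var = s**2
    frac = var / var.sum()
    scores = U * s
    weights = Vt.T
    if reference_map is None:
        reference_map = X[:, 0]
    ref = np.asarray(reference_map, dtype=float)
    for j in range(k):
        if np.ptp(scores[:, j]) == 0 or np.ptp(ref) == 0:
            continue
        r = stats.spearmanr(scores[:, j], ref).statistic
        if np.isfinite(r) and r < 0:
            scores[:, j] *= -1
            weights[:, j] *= -1
    return PCAResult(scores, weights, frac, list(df.columns), list(df.index))


def component_loadings(
    matrix, pca: PCAResult, component: int = 1,
    ensemble: SpinEnsemble = None, q: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Pearson loading on a component, with spin p and FDR."""
    if component > pca.n_components:
        raise ValueError("component index exceeds fitted components")
    df = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    score = pca.score_map(component)
    rows = []
    for name in df.columns:
        col = df[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            rows.append((name, np.nan, np.nan))
            continue
        r = float(stats.pearsonr(col, score).statistic)
        if ensemble is not None:
            _, p = spin_pvalue(col, score, ensemble, statistic="pearson")
        else:
            p = np.nan
        rows.append((name, r, p))
    out = pd.DataFrame(rows, columns=["feature", "loading", "p_spin"]).set_index("feature")
    if ensemble is not None:
        ok = np.isfinite(out["p_spin"].to_numpy())
        adj = np.full(len(out), np.nan)
        rej = np.zeros(len(out), dtype=bool)
        if ok.any():
            rej[ok], adj[ok] = fdr_bh(out["p_spin"].to_numpy()[ok], q=q)
        out["p_fdr"] = adj
        out["significant"] = rej
    return out


def correlate_maps(map_a, map_b, ensemble: SpinEnsemble, statistic: str = "spearman"):
    """Spearman correlation of two maps with its spin p-value."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.size != b.size:
        raise ValueError("maps must share the parcellation")
    return spin_pvalue(a, b, ensemble, statistic=statistic)


def correlate_map_family(
    target_map, other_maps: dict, ensemble: SpinEnsemble,
    statistic: str = "spearman", q: float = 0.05,
) -> pd.DataFrame:
    """Target map vs a declared family of maps, FDR across the family."""
    rows = []
    for name, m in other_maps.items():
        r, p = correlate_maps(target_map, m, ensemble, statistic=statistic)
        rows.append((name, r, p))
    out = pd.DataFrame(rows, columns=["map", "r_s", "p_spin"]).set_index("map")
    rej, adj = fdr_bh(out["p_spin"].to_numpy(), q=q)
    out["p_fdr"] = adj
    out["significant"] = rej
    return out


def procrustes_align(weights_ref: np.ndarray, weights_other: np.ndarray):
    """Orthogonal Procrustes alignment of component weights.

    Returns ``(aligned_other, rotation)`` with ``aligned_other =
    weights_other @ rotation`` minimizing the Frobenius distance to
    ``weights_ref``.
    """
    A = np.asarray(weights_other, dtype=float)
    B = np.asarray(weights_ref, dtype=float)
    if A.shape != B.shape:
        raise ValueError("weight matrices must have identical shape")
    vector_input = A.ndim == 1
    if vector_input:
        A = A[:, None]
        B = B[:, None]
    R, _ = orthogonal_procrustes(A, B)
    aligned = A @ R
    if vector_input:
        return aligned[:, 0], R
    return aligned, R
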