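"""Partial least squares between time-series features and micro-architecture.

Both matrices are z-scored column-wise and the cross-correlation matrix
R = X'Y / (n - 1) is singular-value decomposed, R = U S V'. Each singular
vector pair (latent variable) carries an effect size eta_i = s_i^2 /
sum_j s_j^2; brain scores are the projections XU and YV; loadings are the
Pearson correlations of each original column with its own-side scores.

Inference: latent-variable significance by spatial-autocorrelation-
preserving permutations of X's rows (null distribution of same-ranked
singular values, plus-one p); loading reliability by bootstrap resampling
of parcels with sign alignment to the original singular vectors;
generalizability by distance-dependent cross-validation (75% nearest
parcels to a random seed train, 25% distal test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import split_rng
from .containers import FeatureMatrix, ParcellationGeometry
from .spatialnulls import SpinEnsemble

__all__ = [
    "PLSResult",
    "pls_fit",
    "pls_permutation_test",
    "pls_bootstrap_loadings",
    "distance_dependent_cv",
]


def _as_frame(M, side: str) -> pd.DataFrame:
    if isinstance(M, FeatureMatrix):
        if not M.mask.to_numpy(dtype=bool).all():
            raise ValueError(f"{side} contains invalid entries; aggregate/prune first")
        return M.values
    if isinstance(M, pd.DataFrame):
        return M
    M = np.asarray(M, dtype=float)
    return pd.DataFrame(M, columns=[f"{side}_{j}" for j in range(M.shape[1])])


def _zscore_drop_constant(df: pd.DataFrame, side: str):
    X = df.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(df.columns, keep) if not k]
        warnings.warn(f"dropping constant {side} columns: {dropped}")
    X = X[:, keep]
    if X.shape[1] < 2:
        raise ValueError(f"fewer than 2 usable {side} columns")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return Z, [c for c, k in zip(df.columns, keep) if k]


@dataclass
class PLSResult:
    U: np.ndarray                 # (t, J) left singular vectors
    V: np.ndarray                 # (m, J) right singular vectors
    S: np.ndarray                 # (J,) singular values, nonincreasing
    effect_sizes: np.ndarray      # eta_i = s_i^2 / sum s^2
    x_scores: np.ndarray          # (n, J) = Zx U
    y_scores: np.ndarray          # (n, J) = Zy V
    x_loadings: np.ndarray        # (t, J) corr(X_col, x_score)
    y_loadings: np.ndarray        # (m, J)
    x_names: list = field(default_factory=list)
    y_names: list = field(default_factory=list)
    p_spin: np.ndarray = None
    x_loading_ci: tuple = None    # (lower, upper) each (t, J)
    y_loading_ci: tuple = None

    @property
    def n_lv(self) -> int:
        return self.S.size


def _corr_cols_with_scores(Z: np.ndarray, scores: np.ndarray) -> np.ndarray:
    Zc = Z - Z.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    num = Zc.T @ Sc
    denom = np.sqrt((Zc**2).sum(axis=0))[:, None] * np.sqrt((Sc**2).sum(axis=0))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / denom


def _svd_cross(Zx: np.ndarray, Zy: np.ndarray, n_lv: int):
    n = Zx.shape[0]
    R = (Zx.T @ Zy) / (n - 1)
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    return U[:, :n_lv], s[:n_lv], Vt[:n_lv].T


def pls_fit(X, Y) -> PLSResult:
    """Fit the PLS latent variables of two parcels x columns matrices."""
    xdf = _as_frame(X, "x")
    ydf = _as_frame(Y, "y")
    n = xdf.shape[0]
    if ydf.shape[0] != n:
        raise ValueError("X and Y must share parcels")
    if n < 3:
        raise ValueError("need at least 3 parcels")
    Zx, x_names = _zscore_drop_constant(xdf, "x")
    Zy, y_names = _zscore_drop_constant(ydf, "y")
    n_lv = min(len(x_names), len(y_names), n - 1)
    U, s, V = _svd_cross(Zx, Zy, n_lv)
    eta = s**2 / np.sum(s**2) if np.sum(s**2) > 0 else np.zeros_like(s)
    x_scores = Zx @ U
    y_scores = Zy @ V
    return PLSResult(
        U=U, V=V, S=s, effect_sizes=eta,
        x_scores=x_scores, y_scores=y_scores,
        x_loadings=_corr_cols_with_scores(Zx, x_scores),
        y_loadings=_corr_cols_with_scores(Zy, y_scores),
        x_names=x_names, y_names=y_names,
    )


def pls_permutation_test(X, Y, ensemble: SpinEnsemble) -> np.ndarray:
    """Spin-permutation p-value per latent variable.

    X's rows are reindexed by each spin row (Y fixed), the fit repeated,
    and the i-th observed singular value compared with the null
    distribution of i-th singular values (plus-one convention).
    """
    xdf = _as_frame(X, "x")
    ydf = _as_frame(Y, "y")
    if xdf.shape[0] != ensemble.n_parcels:
        raise ValueError("ensemble geometry does not match the data")
    Zx, _ = _zscore_drop_constant(xdf, "x")
    Zy, _ = _zscore_drop_constant(ydf, "y")
    n_lv = min(Zx.shape[1], Zy.shape[1], Zx.shape[0] - 1)
    _, s_obs, _ = _svd_cross(Zx, Zy, n_lv)
    rows = ensemble.indices[1:] if ensemble.include_identity else ensemble.indices
    null_s = np.empty((rows.shape[0], n_lv))
    for i, row in enumerate(rows):
        Zp = Zx[row]
        # re-standardize: duplicated rows change column moments
        sd = Zp.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Zp = (Zp - Zp.mean(axis=0)) / sd
        _, s_null, _ = _svd_cross(Zp, Zy, n_lv)
        null_s[i] = s_null
    p = (1.0 + np.sum(null_s >= s_obs[None, :], axis=0)) / (1.0 + rows.shape[0])
    return p


def pls_bootstrap_loadings(X, Y, n_boot: int = 10000, seed: int = 0, alpha: float = 0.05):
    """Percentile bootstrap CIs for loadings, parcels resampled with replacement.

    Per resample, latent-variable signs are aligned to the original fit by
    maximizing the scalar product of singular vectors, preventing sign
    flips from corrupting the CIs. Returns ``(x_ci, y_ci)``, each a
    ``(lower, upper)`` pair of (columns x LV) arrays.
    """
    base = pls_fit(X, Y)
    xdf = _as_frame(X, "x")[base.x_names]
    ydf = _as_frame(Y, "y")[base.y_names]
    Xv = xdf.to_numpy(dtype=float)
    Yv = ydf.to_numpy(dtype=float)
    n = Xv.shape[0]
    rng = split_rng(seed, "pls_bootstrap")
    xl = np.empty((n_boot,) + base.x_loadings.shape)
    yl = np.empty((n_boot,) + base.y_loadings.shape)
    b = 0
    guard = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        if np.unique(idx).size < 3:
            guard += 1
            if guard > 1000:
                raise RuntimeError("cannot draw a usable bootstrap resample")
            continue
        Xb, Yb = Xv[idx], Yv[idx]
        sdx = Xb.std(axis=0, ddof=1)
        sdy = Yb.std(axis=0, ddof=1)
        if np.any(sdx == 0) or np.any(sdy == 0):
            guard += 1
            if guard > 1000:
                raise RuntimeError("degenerate bootstrap resamples")
            continue
        Zxb = (Xb - Xb.mean(axis=0)) / sdx
        Zyb = (Yb - Yb.mean(axis=0)) / sdy
        Ub, sb, Vb = _svd_cross(Zxb, Zyb, base.n_lv)
        sign = np.sign(np.sum(Ub * base.U, axis=0))
        sign[sign == 0] = 1.0
        Ub = Ub * sign
        Vb = Vb * sign
        xl[b] = _corr_cols_with_scores(Zxb, Zxb @ Ub)
        yl[b] = _corr_cols_with_scores(Zyb, Zyb @ Vb)
        b += 1
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    x_ci = (np.nanpercentile(xl, lo_q, axis=0), np.nanpercentile(xl, hi_q, axis=0))
    y_ci = (np.nanpercentile(yl, lo_q, axis=0), np.nanpercentile(yl, hi_q, axis=0))
    return x_ci, y_ci


def distance_dependent_cv(
    X, Y, geometry: ParcellationGeometry,
    train_frac: float = 0.75, n_splits: int = 99, seed: int = 0, lv: int = 1,
) -> pd.DataFrame:
    """Distance-dependent train/test splits of parcels.

    Per split: a seed parcel is drawn (without replacement across splits);
    the ``train_frac`` nearest parcels by Euclidean centroid distance
    (seed included) train the PLS; the distal remainder is projected onto
    the train singular vectors (standardized with train-side means/SDs, no
    leakage) and the Spearman correlation between LV ``lv`` X- and
    Y-scores is recorded for both sets.
    """
    xdf = _as_frame(X, "x")
    ydf = _as_frame(Y, "y")
    n = xdf.shape[0]
    if geometry.n_parcels != n:
        raise ValueError("geometry does not match the data")
    if n_splits > n:
        raise ValueError("n_splits cannot exceed the number of parcels")
    Xv = xdf.to_numpy(dtype=float)
    Yv = ydf.to_numpy(dtype=float)
    rng = split_rng(seed, "ddcv")
    seeds = rng.choice(n, size=n_splits, replace=False)
    n_train = int(round(train_frac * n))
    rows = []
    for sp, sd_parcel in enumerate(seeds):
        d = np.linalg.norm(geometry.centroids - geometry.centroids[sd_parcel], axis=1)
        order = np.argsort(d, kind="stable")
        train = order[:n_train]
        test = order[n_train:]
        Xtr, Ytr = Xv[train], Yv[train]
        mx, sx = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
        my, sy = Ytr.mean(axis=0), Ytr.std(axis=0, ddof=1)
        sx[sx == 0] = 1.0
        sy[sy == 0] = 1.0
        Zx_tr = (Xtr - mx) / sx
        Zy_tr = (Ytr - my) / sy
        n_lv = min(Zx_tr.shape[1], Zy_tr.shape[1], Zx_tr.shape[0] - 1)
        U, s, V = _svd_cross(Zx_tr, Zy_tr, n_lv)
        j = lv - 1
        tr_x, tr_y = Zx_tr @ U[:, j], Zy_tr @ V[:, j]
        Zx_te = (Xv[test] - mx) / sx
        Zy_te = (Yv[test] - my) / sy
        te_x, te_y = Zx_te @ U[:, j], Zy_te @ V[:, j]
        r_tr = stats.spearmanr(tr_x, tr_y).statistic
        r_te = stats.spearmanr(te_x, te_y).statistic
        rows.append((int(sd_parcel), float(r_tr), float(r_te)))
    return pd.DataFrame(rows, columns=["seed_parcel", "train_r", "test_r"])
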