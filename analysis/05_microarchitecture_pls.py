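#!/usr/bin/env python
"""PLS between time-series features and micro-architectural maps.

Latent variables of the feature-by-micro-map cross-correlation, their
effect sizes and spin-permutation p-values, bootstrap CIs for the
loadings, and the distance-dependent 75/25 cross-validation of LV1
brain-score correlations.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from megdyn import io as mio
from megdyn.pipeline import RunConfig
from megdyn.plsmap import (
    distance_dependent_cv,
    pls_bootstrap_loadings,
    pls_fit,
    pls_permutation_test,
)
from megdyn.spatialnulls import make_spin_ensemble

ap = argparse.ArgumentParser()
ap.add_argument("--out", type=str, default="results/demo")
args = ap.parse_args()
out = Path(args.out)

cfg = RunConfig.from_json(out / "config.json")
geometry = mio.read_geometry(out / "geometry.tsv")
X = mio.read_feature_matrix(out / "features_group.tsv",
                            normalization="sigmoid-scaled")
Y = pd.read_csv(out / "micro_maps.tsv", sep="\t", index_col=0)

fit = pls_fit(X, Y)
ensemble = make_spin_ensemble(geometry, n_perms=cfg.n_perms, seed=cfg.seed)
fit.p_spin = pls_permutation_test(X, Y, ensemble)
print(f"LV1 explains {100*fit.effect_sizes[0]:.1f}% of the cross-covariance "
      f"(p_spin = {fit.p_spin[0]:.4f})")
r_scores = stats.spearmanr(fit.x_scores[:, 0], fit.y_scores[:, 0]).statistic
print(f"LV1 brain-score correlation: r_s = {r_scores:.3f}")

x_ci, y_ci = pls_bootstrap_loadings(X, Y, n_boot=cfg.n_boot, seed=cfg.seed)
loadings = pd.DataFrame({
    "loading": fit.y_loadings[:, 0],
    "ci_lo": y_ci[0][:, 0],
    "ci_hi": y_ci[1][:, 0],
}, index=fit.y_names)
loadings.to_csv(out / "pls_micro_loadings.tsv", sep="\t")
robust = loadings[(loadings["ci_lo"] > 0) | (loadings["ci_hi"] < 0)]
print(f"{len(robust)}/{len(loadings)} micro-map loadings have 95% bootstrap "
      "CIs excluding zero")

cv = distance_dependent_cv(X, Y, geometry, n_splits=cfg.n_splits, seed=cfg.seed)
cv.to_csv(out / "pls_cv.tsv", sep="\t", index=False)
print(f"distance-dependent CV over {len(cv)} splits: "
      f"train mean r_s = {cv['train_r'].mean():.3f}, "
      f"test mean r_s = {cv['test_r'].mean():.3f}")

pd.DataFrame({
    "lv": np.arange(1, fit.n_lv + 1),
    "singular_value": fit.S,
    "effect_size": fit.effect_sizes,
    "p_spin": fit.p_spin,
}).to_csv(out / "pls_lvs.tsv", sep="\t", index=False)
pd.DataFrame({
    "parcel_id": geometry.parcel_ids,
    "x_score_lv1": fit.x_scores[:, 0],
    "y_score_lv1": fit.y_scores[:, 0],
}).to_csv(out / "pls_scores.tsv", sep="\t", index=False)
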