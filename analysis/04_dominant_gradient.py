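#!/usr/bin/env python
"""Dominant gradient of neurophysiological dynamics.

PCA of the group feature matrix; PC1 scores form the gradient map, its
loadings (feature-to-score correlations with spin significance, FDR)
describe the feature composition, and the gradient is contextualized
against the canonical band-power maps and intrinsic timescale.
"""

import argparse
from pathlib import Path

import pandas as pd
from scipy import stats

from megdyn import io as mio
from megdyn.gradients import component_loadings, correlate_map_family, fit_pca
from megdyn.pipeline import RunConfig
from megdyn.spatialnulls import make_spin_ensemble

ap = argparse.ArgumentParser()
ap.add_argument("--out", type=str, default="results/demo")
args = ap.parse_args()
out = Path(args.out)

cfg = RunConfig.from_json(out / "config.json")
geometry = mio.read_geometry(out / "geometry.tsv")
latent, _ = mio.read_map(out / "latent_map.tsv", name="latent")
group = mio.read_feature_matrix(out / "features_group.tsv",
                                normalization="sigmoid-scaled")
spectral = pd.read_csv(out / "spectral_maps.tsv", sep="\t", index_col=0)

ensemble = make_spin_ensemble(geometry, n_perms=cfg.n_perms, seed=cfg.seed)
pca = fit_pca(group, reference_map=latent)
print(f"PC1 captures {100*pca.variance_explained[0]:.1f}% of feature variance "
      f"(PC2: {100*pca.variance_explained[1]:.1f}%)")
rho = stats.spearmanr(pca.score_map(1), latent).statistic
print(f"PC1 vs generating latent gradient: r_s = {rho:.3f}")

loadings = component_loadings(group, pca, component=1, ensemble=ensemble)
loadings.to_csv(out / "pc1_loadings.tsv", sep="\t")
top = loadings["loading"].abs().sort_values(ascending=False).head(8)
print("top |loading| features:")
for name in top.index:
    row = loadings.loc[name]
    print(f"  {name:28s} r={row['loading']:+.3f} p_spin={row['p_spin']:.4f}")

fam = {c: spectral[c].to_numpy() for c in
       ("delta", "theta", "alpha", "beta", "lo_gamma", "hi_gamma")}
fam["timescale"] = spectral["timescale_s"].to_numpy()
comp = correlate_map_family(pca.score_map(1), fam, ensemble)
comp.to_csv(out / "pc1_map_comparisons.tsv", sep="\t")
print("PC1 vs canonical maps (FDR across the 7 comparisons):")
print(comp.round(4).to_string())

mio.write_map(pca.score_map(1), geometry.parcel_ids, out / "pc1_scores.tsv",
              name="pc1")
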