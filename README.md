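# megdyn

Phenotyping of regional neurophysiological dynamics and their mapping
onto cortical micro-architecture.

Resting-state electrophysiological recordings (MEG-like source signals)
carry a rich dynamical fingerprint per brain region: power-spectral
shape, autocorrelation structure, fractal scaling, entropy, and more.
`megdyn` implements the full analysis chain that (i) extracts a curated
bank of ~100 time-series features per parcel, (ii) finds the dominant
spatial gradient of those dynamics by PCA, and (iii) statistically maps
the dynamics onto a multimodal bank of micro-architectural brain maps
using partial least squares (PLS) with spatial-autocorrelation-
preserving "spin" nulls, bootstrap confidence intervals, and
distance-dependent cross-validation — all exercised end to end on
synthetic cohorts with known ground truth, so every stage is testable
without any external data download.

## The models at the core

**Spectral parameterization.** Each region's Welch power spectrum
(4 s Hann windows, 50% overlap) is decomposed in log10 space into an
aperiodic component and Gaussian oscillatory peaks:

    log10 P(f) = b − log10(k + f^χ) + Σ_j h_j exp(−(f − c_j)² / 2w_j²)

with offset *b*, knee *k*, exponent *χ*, fit over 1–60 Hz in knee mode
(peak width limits 1–6 Hz, ≤ 6 peaks, minimum peak height 0.1, peak
threshold 2). The knee frequency is *f_k* = *k*^(1/χ) and the intrinsic
neural timescale τ = 1/(2π f_k). Band-limited oscillation scores
multiply the normalized group-mean peak-power map with the peak-detection
probability map.

**Feature normalization.** Each feature is normalized across parcels
with the outlier-robust sigmoid x_norm = 1/(1 + exp(−(x − ⟨x⟩)/IQR)),
⟨x⟩ the median (IQR optionally divided by 1.35 for Gaussian-consistent
slope), then rescaled to [0, 1]; features that error for any participant
are pruned; per-participant matrices are averaged into the group
parcels × features matrix.

**PLS.** With column-z-scored X (parcels × features) and Y (parcels ×
micro-maps), the cross-correlation R = X′Y/(n−1) = USV′ yields latent
variables with effect sizes η_i = s_i²/Σ_j s_j², brain scores XU and YV,
and loadings = Pearson correlations of the inputs with their own-side
scores. Significance: spin permutations of X's rows (null distribution
of same-ranked singular values). Reliability: bootstrap resampling of
parcels with sign-aligned LVs. Generalizability: 75% of parcels nearest
a random seed parcel train the model, the 25% most distal test it.

**Spin nulls.** Uniform random rotations (quaternion-sampled) act on
each hemisphere's own equal-area spherical projection; the rotation is
mirrored onto the other hemisphere; parcel values are reassigned by the
nearest rotated centroid. p-values use the plus-one permutation
convention (never exactly 0); FDR is Benjamini–Hochberg.

**Expression processing.** Multi-donor probe-level data pass a
background-intensity filter (discard when below background in ≥ 50% of
samples), per-gene probe selection by differential stability
ΔS(p) = mean over donor pairs of Spearman ρ between regional profiles,
two-stage robust-sigmoid normalization (across genes within sample,
then across samples within gene), mirrored nearest-centroid sample
assignment with inverse-distance fill of empty parcels, and gene-set
averaging into cell-class maps.

## Worked example

The numbered drivers under `analysis/` run the full demo study
(100 parcels, 6 participants, 80 s analyzed at 509 Hz after dropping
30 s, 45 micro-maps, 1 000 spins):

```bash
python analysis/01_simulate.py --seed 1 --out results/demo
python analysis/02_spectral_maps.py
python analysis/03_timeseries_features.py
python analysis/04_dominant_gradient.py
python analysis/05_microarchitecture_pls.py
python analysis/06_snr_and_noise_controls.py
python analysis/07_expression_maps.py
python analysis/08_null_calibration.py
```

With seed 1 this prints, among other things:

```
group timescale range: 7.8 - 12.8 ms
timescale vs latent gradient: r_s = -0.981
catalog: 101 features; 101 survived error pruning across 6 participants
PC1 captures 63.6% of feature variance (PC2: 7.5%)
PC1 vs generating latent gradient: r_s = 0.993
LV1 explains 95.2% of the cross-covariance (p_spin = 0.0899)
LV1 brain-score correlation: r_s = 0.937
distance-dependent CV over 99 splits: train mean r_s = 0.921, test mean r_s = 0.824
SNR filter removed 5/101 features (uncorrected p_spin < 0.05)
empty-room aligned PC1 vs rest PC1: r_s = 0.074, p_spin = 0.480
spin test type-I error at alpha=0.05: 0.056 (KS vs uniform 0.035)
```

Reading these numbers: the dominant principal component of the feature
matrix recovers the latent cortical gradient the generator injected
(r_s = 0.99) and captures most feature variance; the first PLS latent
variable dominates the feature–micro-architecture cross-covariance and
its brain-score coupling survives out-of-sample projection (test
r_s = 0.82 < train 0.92, as expected under noise); the dynamics gradient
is unrelated to instrument-noise structure (empty-room comparison near
zero, non-significant); and the spin test controls its false-positive
rate near the nominal 5%.

Equivalently, `megdyn.pipeline.run_pipeline(RunConfig(...))` executes
all stages in one call and writes a manifest with the config digest.

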