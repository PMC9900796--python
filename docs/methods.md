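# Methods

This note documents the models, the synthetic study design, the
numerical choices, and the limitations of `megdyn`. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Synthetic study design

All analyses run on generated data with known ground truth. The design
emulates a resting-state MEG study at desk scale:

- **Parcellation.** 2·n quasi-uniform centroids on the unit sphere
  (Fibonacci-style lattice per hemisphere, right hemisphere the x-mirror
  of the left). The demo uses n = 50 per hemisphere (100 parcels).
- **Latent gradient.** One smooth scalar map (Gaussian process,
  squared-exponential covariance, zero mean, unit variance) plays the
  role of a unimodal–transmodal cortical hierarchy. Demo lengthscale:
  0.8 rad.
- **Regional signals.** Per region, Gaussian noise is spectrally shaped
  in the frequency domain to the target one-sided PSD
  10^b/(k + f^χ) plus Gaussian-envelope oscillatory peaks, so the target
  spectrum holds exactly in expectation. The knee (base 250, slope 70
  per latent SD), alpha-peak frequency (10 ± 1.5 Hz) and peak amplitude
  ride the latent map linearly; slopes leave a positivity margin at
  |latent| ≈ 3. The demo cohort is 6 participants × 110 s at 509 Hz;
  the first 30 s are dropped and 80 s analyzed, matching the sampling
  protocol the analysis stages assume. A participant-jitter parameter
  multiplies knee and peak amplitude by 1 + jitter·N(0,1); it defaults
  to 0.05 in the library and 0 in the demo, and makes no claim of
  fidelity to empirical between-participant variability.
- **Micro-architecture bank.** 45 maps, each coupling·w_j·latent plus
  √(1 − coupling²) of an independent smooth map (demo coupling 0.7) —
  a bank of spatially autocorrelated maps sharing one latent factor with
  the dynamics.
- **Rank-1 coupled feature sets.** For parameter-recovery and
  calibration experiments, X = c·z·w_x′ + σ·ε and Y = c·z·w_y′ + σ·ε
  with z a smooth latent map. Weight entries are unit-magnitude random
  signs: column-wise z-scoring (which every consumer applies) preserves
  exactly this weight direction, so the stored ground truth is the
  quantity a correct fit should recover.
- **Donor expression.** Each probe has a shared smooth regional profile;
  donor d observes √r·shared + √(1−r)·donor-specific noise
  (r = reliability, demo 0.8), so reliability 1 gives differential
  stability exactly 1 and reliability 0 gives mean DS ≈ 0. Samples sit
  at region centroids scaled to 100 mm, with per-donor coverage 85% and
  a 10% below-background rate.
- **Empty-room recordings.** The same signal generator with a flat
  spatial profile (no gradient, no peaks, shallow 1/f) stands in for
  environmental/instrument noise.

All randomness derives from one integer seed through counter-based
(Philox) streams split by stage name, so regeneration is bitwise
reproducible and modules can be tested independently.

## Geometry, spin nulls, and why smoothness lives on a projection sphere

Spin permutations must rotate a space that is *closed* under rotation.
Rotating the centroids of a half-sphere hemisphere leaves an uncovered
crescent in which the nearest-centroid reassignment collapses many
parcels onto few (we measured ~50% duplicated indices per permutation
and a correspondingly inflated false-positive rate). Surface-based spin
tests avoid this because each hemisphere is inflated to its own full
sphere. `megdyn` adopts the same convention: an equal-area map (azimuth
doubling at constant z) sends the left half-sphere onto a full sphere;
rotations act there, the right hemisphere is mirrored into the left
frame first, and mirror-twin parcels share a projected position.
Consistently, the smooth-map generator defines its covariance in this
projected space, which makes generated maps bilaterally symmetric —
the same symmetry the mirrored-rotation null convention assumes, and
the same one used when expression samples are mirrored across
hemispheres. After this design choice the spin test's type-I error on
independent smooth map pairs is 0.04–0.08 at α = 0.05 (the acceptance
suite checks the band [0.03, 0.08]), and the PLS permutation p-value is
uniform under zero coupling.

Null-calibration experiments use lengthscale 0.5 rad — moderately
smooth maps (~30° correlation length), chosen once as representative of
parcellated cortical maps; very smooth maps (≥ 0.8 rad) retain so few
spatial degrees of freedom that any spatial null grows conservative and
slightly anticonservative in the tails, a known property of
nearest-neighbour spin tests rather than an implementation artifact.

## Spectral parameterization

The knee-mode fit works in log10 power over 1–60 Hz: (1) a robust
aperiodic fit b − log10(k + f^χ) (bounded nonlinear least squares,
three starts at χ ∈ {0.5, 1.5, 2.5} because the knee model has local
minima; a second pass excludes points whose positive residual exceeds
one MAD, i.e. candidate peaks); (2) Gaussian peaks extracted
largest-first from the flattened residual until 6 peaks or the residual
maximum falls below max(2·SD, 0.1), followed by a joint refit of all
peaks with width SD bounded by half the 1–6 Hz bandwidth limits — peaks
whose jointly-refit height drops below the 0.1 minimum are discarded as
noise excursions; (3) a final aperiodic refit on the peak-removed
spectrum, and R² of the full model in log-log space. Analytic Jacobians
make the fit ~40 ms per spectrum.

Operating characteristics measured by the acceptance suite: on
noiseless model-generated spectra, (k, χ) are recovered to machine
precision (≪ 2%); on single 80 s Welch estimates the per-region τ error
is ~5% median (estimator variance at 39 windows), and the cohort-median
τ map over 6 participants is accurate to ~3% median — the cohort-level
map is the quantity the pipeline reports.

The oscillation score uses the fitted peak height (log10-power units
above the aperiodic curve) as "peak power", averages over participants
*with* a detection (the probability factor already penalizes
non-detection), normalizes by the maximum over parcels, and multiplies
by the detection-probability map. Gamma bands are excluded from
oscillation scores (no consistent gamma peaks are detectable); total
power covers all six canonical bands (δ 2–4, θ 5–7, α 8–12, β 15–29,
lo-γ 30–59, hi-γ 60–90 Hz; adjusted bands α 8–14, β 15–30 Hz).

## Feature catalog

101 deterministic features over seven families (distribution,
autocorrelation, forecasting, fluctuation, wavelet, entropy, spectral),
standing in for massive-extraction toolboxes: the scientific claims
tested here concern feature *families* and specific highlighted
features (long-lag autocorrelation, ACF zero crossing, rolling linear
forecast residuals, DFA exponents and variants, wavelet energies, band
powers), not a census. Notable conventions:

- sample ACF uses the biased 1/N normalization (valid correlation
  sequence), computed once per signal via FFT and cached;
- lags given in seconds convert with round-half-up (24 steps = 48 ms at
  ~500 Hz);
- DFA integrates the de-meaned signal, detrends non-overlapping windows
  with order-1 (variants: order-2, mean-abs fluctuation) polynomials at
  18 log-spaced scales from 8 to n/4 samples, and reports the log-log
  slope; fluctuations at rounding level (≤ 1e-10 of the profile RMS)
  flag the result invalid, as do scale sets not spanning a decade;
- failures (undefined statistics, degenerate signals) are flagged
  invalid, never raised, and invalid-anywhere features are pruned from
  the group matrix;
- the segment-length stability analysis uses nested-from-start segments
  (5–125 s in 5 s steps, truncated with a warning on shorter
  recordings) and a 22-feature fast subset of the catalog.

The robust-sigmoid normalization divides the IQR by 1.35 for feature
matrices (sigmoid slope matched to a unit-SD Gaussian, the common
toolbox convention) and uses the bare IQR in the expression pathway,
exactly as the two-stage expression normalization is conventionally
printed; both constants are exposed as parameters.

## PLS and inference

R = X′Y/(n−1) on z-scored columns, so entries are exactly Pearson
correlations; the scalar factor rescales singular values but leaves
U, V, effect sizes and p-values unchanged. The number of latent
variables is min(t, m, n−1). Permutations spin X's rows only (breaking
the pairing once suffices, and each side's autocorrelation is
preserved); permuted columns are re-standardized because duplicated
rows change column moments; no Procrustes realignment is applied in the
significance test (the null compares same-ranked singular values).
Bootstrap resamples parcels with replacement, realigns LV signs by the
scalar product with the original singular vectors, and takes percentile
2.5/97.5 CIs; resamples with fewer than 3 distinct parcels are redrawn.
Distance-dependent CV standardizes test rows with train-side means/SDs
(no leakage); seeds are drawn without replacement, so 99 splits is the
maximum for 100 parcels.

Measured operating characteristics (acceptance suite): LV1 weight
recovery |r| ≈ 0.99 median at coupling 0.9, noise SD 0.5, 100 parcels;
permutation p uniform under zero coupling (KS ≈ 0.05 at 200 × 500);
bootstrap 95% CI coverage 93–95% of the closed-form population loading
in an exchangeable-correlation design (the population loading of a
column on the equal-weight score is (1+(t−1)ρ)/√(t+t(t−1)ρ) with
ρ = 0.64, t = 20).

## Confound controls

The SNR forward model is SNR = 10 log10((a²/N) Σ_k b_k²/s_k²) dB with
a = 10 nAm by default. Feature filtering removes features whose Pearson
correlation with the SNR map has uncorrected spin p < 0.05 — kept
verbatim as the conservative removal rule (correction would remove
fewer); an FDR-based alternative sits behind a flag. Regression removes
intercept + SNR by OLS per feature; residuals are exactly orthogonal to
the centered covariate. The empty-room comparison intersects the valid
feature sets, fits PCA to both, Procrustes-aligns the noise weights to
the rest weights, and spin-tests the aligned PC1 score maps. A global
sign flip of a data matrix flips its score map regardless of weight
alignment — component sign is arbitrary and inference is two-sided.

## Expression pathway

Probes below background in ≥ 50% of pooled samples are discarded
(exactly-50% discards). Differential stability is the mean over all
donor pairs of the Spearman correlation between regional profiles
(regions with samples from both donors; ≥ 3 required); the max-DS probe
represents each gene. Normalization is applied per donor, first across
genes within each sample, then across samples within each gene; the
two-stage scheme is order-dependent and deliberately not idempotent.
Samples (and their x-mirrored copies) are assigned to the nearest
centroid within a threshold that defaults to half the median
nearest-neighbour centroid spacing — the areal "within 2 mm of a
parcel" rule has no literal analogue for point centroids, and this
default preserves its role (assign near, exclude far) at centroid
resolution while remaining configurable. Parcels with samples average
donor-wise then across donors; empty parcels are filled by
inverse-distance weighting over all normalized samples, a centroid-level
analogue of dense voxel interpolation. Cell-class maps are unweighted
gene-set means.

## Sizes and determinism

The demo (100 parcels, 6 participants, 80 s analyzed, 1 000 spins, 500
bootstraps, 99 CV splits) completes in a few minutes on one CPU; the
calibration experiments (500 × 1 000 spin replicates, 200 × 500
permutation replicates, 200 × 500 bootstrap replicates) add a few more.
These sizes were chosen so the full validation runs interactively while
keeping Monte-Carlo error well inside the tested tolerance bands. Rerun
with the same config, every output file is byte-identical; the manifest
records the config digest so outputs of different configs cannot be
silently mixed.

## Known limitations

- The generator produces linear Gaussian signals; features sensitive to
  nonlinearity or non-Gaussianity take near-baseline values, so passing
  tests say nothing about those features' behaviour on real recordings.
- Generated maps are exactly bilaterally symmetric; real cortical maps
  are only approximately so, and real spin nulls inherit distortions
  from surface inflation that the synthetic projection only mimics.
- The τ estimator's ~5% single-recording error is dominated by Welch
  variance at 80 s; longer recordings or more participants tighten it.
- The expression pathway operates at centroid resolution; ontology-
  constrained sample matching and voxel-level interpolation are outside
  the synthetic setting.
- No sensor-level forward modelling: SNR gains are synthetic scalars,
  not head-model leadfields.
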