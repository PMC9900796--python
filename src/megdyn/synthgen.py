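"""Synthetic data generators with known ground truth.

Everything downstream (spectral fitting, feature extraction, gradients,
PLS, expression processing) is exercised on data produced here, so each
generator is a pure function of its seed and parameters and exposes the
latent structure it injected.

The regional signal generator produces source-like activity whose power
spectrum follows the periodic + aperiodic model

    P(f) = 10**b / (k + f**chi)  +  Gaussian-envelope oscillatory peaks,

with the aperiodic parameters (offset b, knee k, exponent chi) and the
peak parameters varying linearly along a smooth latent cortical map.
Spectral shaping is done by frequency-domain amplitude modulation of white
Gaussian noise, so the target PSD holds exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._rng import split_rng
from .containers import (
    FeatureMatrix,
    ParcellationGeometry,
    RegionalTimeSeriesSet,
    SyntheticGroundTruth,
)

__all__ = [
    "gen_parcellation",
    "gen_smooth_map",
    "AperiodicProfile",
    "PeakSpec",
    "gen_regional_timeseries",
    "gen_empty_room",
    "gen_coupled_feature_sets",
    "gen_micro_maps",
    "gen_donor_expression",
    "DonorExpressionSet",
]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def gen_parcellation(n_per_hemisphere: int, seed: int = 0) -> ParcellationGeometry:
    """Quasi-uniform centroids per hemisphere; right is the x-mirror of left.

    The left hemisphere occupies the x < 0 half-sphere and is laid out on a
    Fibonacci-style lattice (area-preserving map of a low-discrepancy
    sequence onto the half-sphere). ``n_per_hemisphere == 1`` degenerates
    to a single centroid at each x-pole.
    """
    n = int(n_per_hemisphere)
    if n < 1:
        raise ValueError("n_per_hemisphere must be >= 1")
    if n == 1:
        left = np.array([[-1.0, 0.0, 0.0]])
    else:
        i = np.arange(n)
        u = np.mod(i / _GOLDEN, 1.0)          # azimuthal fraction
        v = (i + 0.5) / n                      # area fraction (polar)
        # azimuth strictly inside (pi/2, 3pi/2) so x < 0: a small margin
        # keeps lattice points off the midline (no cross-hemisphere twins)
        eps = 0.5 / n
        phi = np.pi / 2.0 + np.pi * (eps + (1.0 - 2.0 * eps) * u)
        z = 1.0 - 2.0 * v
        s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
        left = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
        left /= np.linalg.norm(left, axis=1, keepdims=True)
    right = left * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([left, right])
    hemisphere = np.array(["L"] * n + ["R"] * n, dtype=object)
    parcel_ids = [f"L{i:03d}" for i in range(n)] + [f"R{i:03d}" for i in range(n)]
    return ParcellationGeometry(centroids, hemisphere, parcel_ids)


def great_circle_distance(a: np.ndarray, b: np.ndarray = None) -> np.ndarray:
    """Pairwise great-circle distance (radians) between unit vectors."""
    if b is None:
        b = a
    dots = np.clip(a @ b.T, -1.0, 1.0)
    return np.arccos(dots)


_MIRROR_X = np.diag([-1.0, 1.0, 1.0])


def hemi_projection(points: np.ndarray) -> np.ndarray:
    """Equal-area map of the left (x < 0) half-sphere onto a full sphere.

    Each hemisphere owns its own spherical projection (the surface-analysis
    convention): the azimuth range (pi/2, 3pi/2) is doubled to (0, 2pi) at
    constant z, which preserves area and is bijective on the open half.
    Rotations act on the projected sphere without leaving gaps, which is
    what makes spin permutations well posed.
    """
    z = np.clip(points[:, 2], -1.0, 1.0)
    phi = np.mod(np.arctan2(points[:, 1], points[:, 0]), 2 * np.pi)
    phi2 = 2.0 * (phi - np.pi / 2.0)
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([s * np.cos(phi2), s * np.sin(phi2), z])


def projected_coords(geometry: ParcellationGeometry) -> np.ndarray:
    """Per-parcel coordinates on the hemisphere's projection sphere.

    Right-hemisphere centroids are mirrored into the left half first, so
    homologous (mirror-twin) parcels share one projected position — the
    bilateral-symmetry convention under which one-hemisphere rotations are
    mirrored to the other.
    """
    pts = geometry.centroids.copy()
    right = geometry.hemi_indices("R")
    pts[right] = pts[right] @ _MIRROR_X
    return hemi_projection(pts)


def gen_smooth_map(
    geometry: ParcellationGeometry,
    lengthscale: float,
    seed: int,
    stream: str = "smooth_map",
    standardize: bool = True,
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian-process map on the sphere.

    Squared-exponential covariance in great-circle distance; the kernel
    matrix is eigendecomposed and tiny negative eigenvalues (the SE kernel
    of geodesic distance is not guaranteed PSD on the sphere) are clipped.
    ``standardize=False`` returns the de-meaned raw draw (whose variance
    collapses as the lengthscale grows large).

    Smoothness is defined on the per-hemisphere projection sphere (the
    space in which spin rotations are isometries), with mirror-twin
    parcels perfectly correlated — i.e., maps are bilaterally symmetric,
    matching the convention of mirroring one hemisphere's rotation onto
    the other.
    """
    if lengthscale <= 0:
        raise ValueError("lengthscale must be positive")
    d = great_circle_distance(projected_coords(geometry))
    cov = np.exp(-(d**2) / (2.0 * lengthscale**2))
    cov[np.diag_indices_from(cov)] += 1e-10
    w, e = np.linalg.eigh(cov)
    # the geodesic SE kernel is not guaranteed PSD on the sphere; small
    # negative eigenvalues are expected and clipped, gross ones are a bug
    if w.min() < -1e-2 * w.max():
        raise FloatingPointError(
            f"covariance strongly non-PSD after jitter (min eig {w.min():.3g})"
        )
    w = np.clip(w, 0.0, None)
    rng = split_rng(seed, stream)
    draw = e @ (np.sqrt(w) * rng.standard_normal(geometry.n_parcels))
    draw = draw - draw.mean()
    if standardize:
        sd = draw.std()
        if sd > 0:
            draw = draw / sd
    return draw


# ---------------------------------------------------------------------------
# regional time-series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AperiodicProfile:
    """Aperiodic spectrum 10**b / (k + f**chi), linear in the latent map.

    Per-region value of each parameter is ``base + slope * latent``.
    Units: offset in log10 power density, knee in Hz**chi, exponent
    dimensionless.
    """

    offset: float = 0.0
    knee: float = 100.0
    exponent: float = 2.0
    offset_slope: float = 0.0
    knee_slope: float = 0.0
    exponent_slope: float = 0.0

    def per_region(self, latent: np.ndarray):
        b = self.offset + self.offset_slope * latent
        k = self.knee + self.knee_slope * latent
        chi = self.exponent + self.exponent_slope * latent
        if np.any(k <= 0) or np.any(chi <= 0):
            raise ValueError("knee and exponent must stay positive across regions")
        return b, k, chi


@dataclass(frozen=True)
class PeakSpec:
    """One oscillatory spectral peak (Gaussian envelope in frequency).

    ``height`` is linear power density at the peak centre; centre/height
    vary linearly with the latent map via the slope fields.
    """

    center: float  # Hz
    height: float  # power density units
    width: float   # Hz (Gaussian SD)
    center_slope: float = 0.0
    height_slope: float = 0.0


def _target_psd(freqs, b, k, chi, peaks, latent_value):
    psd = 10.0**b / (k + np.maximum(freqs, 0.0) ** chi)
    for p in peaks:
        c = p.center + p.center_slope * latent_value
        h = p.height + p.height_slope * latent_value
        if h <= 0:
            continue
        psd = psd + h * np.exp(-((freqs - c) ** 2) / (2.0 * p.width**2))
    return psd


def gen_regional_timeseries(
    geometry: ParcellationGeometry,
    duration_s: float,
    fs_hz: float,
    aperiodic_profile: AperiodicProfile = AperiodicProfile(),
    peak_profile: tuple = (),
    seed: int = 0,
    latent_map: np.ndarray = None,
    n_participants: int = 1,
    participant_jitter: float = 0.0,
) -> RegionalTimeSeriesSet:
    """Spectrally shaped Gaussian signals, one per region per participant.

    Each region's one-sided target PSD is the aperiodic curve plus the
    oscillatory peaks, all parameterized by the latent map. Participant
    jitter multiplies knee and peak heights by ``1 + jitter * N(0,1)``
    (clipped to stay positive), emulating between-participant variability
    without any claim of fidelity to empirical cohorts.
    """
    n_samples = int(round(duration_s * fs_hz))
    if n_samples < 2 * fs_hz:
        raise ValueError("need at least 2 s of signal")
    nyq = fs_hz / 2.0
    for p in peak_profile:
        if p.center + 2 * p.width >= nyq:
            raise ValueError(
                f"peak at {p.center} Hz (width {p.width}) violates Nyquist {nyq} Hz"
            )
    latent = np.zeros(geometry.n_parcels) if latent_map is None else np.asarray(latent_map)
    b, k, chi = aperiodic_profile.per_region(latent)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    data = np.empty((n_participants, geometry.n_parcels, n_samples))
    for s in range(n_participants):
        rng = split_rng(seed, "timeseries", s)
        jit_k = 1.0
        jit_h = 1.0
        if participant_jitter > 0:
            jit_k = max(0.1, 1.0 + participant_jitter * rng.standard_normal())
            jit_h = max(0.0, 1.0 + participant_jitter * rng.standard_normal())
        for r in range(geometry.n_parcels):
            peaks = [
                replace(p, height=p.height * jit_h) for p in peak_profile
            ]
            psd = _target_psd(freqs, b[r], k[r] * jit_k, chi[r], peaks, latent[r])
            # amplitude per rFFT bin so the one-sided periodogram matches psd
            amp = np.sqrt(psd * fs_hz * n_samples / 2.0)
            re = rng.standard_normal(freqs.size)
            im = rng.standard_normal(freqs.size)
            spec = amp * (re + 1j * im) / np.sqrt(2.0)
            spec[0] = 0.0  # zero mean by construction
            if n_samples % 2 == 0:
                spec[-1] = amp[-1] * re[-1]
            x = np.fft.irfft(spec, n=n_samples)
            data[s, r] = x - x.mean()
    return RegionalTimeSeriesSet(data=data, fs=fs_hz)


def gen_empty_room(
    geometry: ParcellationGeometry,
    duration_s: float,
    fs_hz: float,
    seed: int = 0,
    n_participants: int = 1,
) -> RegionalTimeSeriesSet:
    """Empty-room-like noise: identical shallow-sloped spectrum everywhere.

    No latent gradient and no oscillatory peaks, emulating environmental /
    instrumental noise recordings.
    """
    profile = AperiodicProfile(offset=-1.0, knee=25.0, exponent=1.0)
    return gen_regional_timeseries(
        geometry,
        duration_s,
        fs_hz,
        aperiodic_profile=profile,
        peak_profile=(),
        seed=seed + 7919,
        latent_map=None,
        n_participants=n_participants,
    )


# ---------------------------------------------------------------------------
# coupled feature sets (rank-1 latent model for PLS recovery)
# ---------------------------------------------------------------------------

def gen_coupled_feature_sets(
    geometry: ParcellationGeometry,
    n_ts_features: int,
    n_micro_features: int,
    coupling_strength: float,
    noise_sd: float,
    seed: int,
    lengthscale: float = 0.8,
    latent_map: np.ndarray = None,
):
    """Rank-1 latent model: X = coupling * z w_x' + noise, same for Y.

    Returns ``(FeatureMatrix X, DataFrame Y, SyntheticGroundTruth)``. The
    latent map z is spatially smooth (or caller-supplied), so the pair is
    a valid substrate for spin-null calibration as well as PLS recovery.
    """
    if n_ts_features < 1 or n_micro_features < 1:
        raise ValueError("need at least one feature per side")
    if not 0.0 <= coupling_strength <= 1.0:
        raise ValueError("coupling_strength must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if latent_map is None:
        z = gen_smooth_map(geometry, lengthscale, seed, stream="coupled_latent")
    else:
        z = np.asarray(latent_map, dtype=float)
    # weight entries are unit-magnitude random signs: column-wise
    # standardization downstream preserves the weight direction exactly,
    # so the stored ground truth is what a correct fit should recover
    rng = split_rng(seed, "coupled_weights")
    wx = rng.choice([-1.0, 1.0], size=n_ts_features) / np.sqrt(n_ts_features)
    wy = rng.choice([-1.0, 1.0], size=n_micro_features) / np.sqrt(n_micro_features)
    nrng = split_rng(seed, "coupled_noise")
    n = geometry.n_parcels
    X = coupling_strength * np.outer(z, wx) + noise_sd * nrng.standard_normal((n, n_ts_features))
    Y = coupling_strength * np.outer(z, wy) + noise_sd * nrng.standard_normal((n, n_micro_features))
    xdf = pd.DataFrame(
        X, index=geometry.parcel_ids, columns=[f"ts_{j:03d}" for j in range(n_ts_features)]
    )
    ydf = pd.DataFrame(
        Y, index=geometry.parcel_ids, columns=[f"micro_{j:03d}" for j in range(n_micro_features)]
    )
    truth = SyntheticGroundTruth(
        latent_map=z, ts_weights=wx, micro_weights=wy, noise_sd=noise_sd, seed=seed
    )
    return FeatureMatrix(xdf), ydf, truth


def gen_micro_maps(
    geometry: ParcellationGeometry,
    latent_map: np.ndarray,
    n_maps: int = 45,
    coupling: float = 0.7,
    lengthscale: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Bank of spatially autocorrelated micro-architecture maps.

    Each map is ``coupling * w_j * z`` plus ``sqrt(1 - coupling^2)`` of an
    independent smooth map, emulating a multimodal atlas sharing a latent
    spatial factor with the dynamics.
    """
    z = np.asarray(latent_map, dtype=float)
    rng = split_rng(seed, "micro_weights")
    w = rng.standard_normal(n_maps)
    w /= np.max(np.abs(w))
    cols = {}
    for j in range(n_maps):
        indep = gen_smooth_map(geometry, lengthscale, seed, stream=f"micro_{j}")
        cols[f"micro_{j:03d}"] = coupling * w[j] * z + np.sqrt(1 - coupling**2) * indep
    return pd.DataFrame(cols, index=geometry.parcel_ids)


# ---------------------------------------------------------------------------
# donor expression
# ---------------------------------------------------------------------------

@dataclass
class DonorExpressionSet:
    """Multi-donor probe x sample expression with background flags.

    ``expression[d]`` is a probes x samples DataFrame for donor d;
    ``above_background[d]`` the matching boolean table; ``sample_coords[d]``
    the (n_samples, 3) coordinates of each tissue sample in the scaled
    (mm-like) space; ``sample_region[d]`` the generating region index
    (ground truth, not used by the processing code); ``probe_genes`` maps
    probe id -> gene symbol.
    """

    expression: dict
    above_background: dict
    sample_coords: dict
    sample_region: dict
    probe_genes: pd.Series
    scale_mm: float = 100.0

    @property
    def donors(self):
        return list(self.expression)

    @property
    def probes(self):
        first = self.expression[self.donors[0]]
        return list(first.index)


def gen_donor_expression(
    n_donors: int,
    n_regions: int,
    n_probes: int,
    reliability: float,
    seed: int,
    geometry: ParcellationGeometry = None,
    coverage: float = 0.85,
    background_rate: float = 0.1,
    scale_mm: float = 100.0,
) -> tuple:
    """Donor-wise probe x sample tables with a shared regional signal.

    Each probe has a shared smooth regional profile; each donor observes
    ``sqrt(r) * shared + sqrt(1-r) * donor-specific`` (r = reliability), so
    reliability 1 gives identical profiles (differential stability 1) and
    reliability 0 gives independent ones (mean DS ~ 0). Samples sit at
    region centroids scaled to ``scale_mm``; a random subset of regions is
    covered per donor. Returns ``(DonorExpressionSet, geometry)``.
    """
    if n_donors < 2:
        raise ValueError("need at least two donors")
    if not 0.0 <= reliability <= 1.0:
        raise ValueError("reliability must be in [0, 1]")
    if n_regions < 3:
        raise ValueError("need at least 3 regions for rank correlations")
    if geometry is None:
        geometry = gen_parcellation(max(2, n_regions // 2), seed=seed)
    n_regions = geometry.n_parcels
    rng = split_rng(seed, "donor_shared")
    shared = rng.standard_normal((n_probes, n_regions))
    # two probes per gene
    genes = pd.Series(
        [f"GENE{j // 2:04d}" for j in range(n_probes)],
        index=[f"probe_{j:04d}" for j in range(n_probes)],
        name="gene",
    )
    expression, above, coords, regions = {}, {}, {}, {}
    for d in range(n_donors):
        drng = split_rng(seed, "donor", d)
        donor_specific = drng.standard_normal((n_probes, n_regions))
        profile = np.sqrt(reliability) * shared + np.sqrt(1.0 - reliability) * donor_specific
        n_cov = max(3, int(round(coverage * n_regions)))
        covered = np.sort(drng.choice(n_regions, size=n_cov, replace=False))
        vals = profile[:, covered]
        donor_id = f"donor{d:02d}"
        sample_ids = [f"{donor_id}_s{i:03d}" for i in range(n_cov)]
        expression[donor_id] = pd.DataFrame(vals, index=genes.index, columns=sample_ids)
        above[donor_id] = pd.DataFrame(
            drng.random((n_probes, n_cov)) >= background_rate,
            index=genes.index,
            columns=sample_ids,
        )
        coords[donor_id] = geometry.centroids[covered] * scale_mm
        regions[donor_id] = covered
    dset = DonorExpressionSet(
        expression=expression,
        above_background=above,
        sample_coords=coords,
        sample_region=regions,
        probe_genes=genes,
        scale_mm=scale_mm,
    )
    return dset, geometry
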