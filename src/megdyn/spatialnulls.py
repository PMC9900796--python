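"""Spatial-autocorrelation-preserving permutation ("spin") nulls.

A spin draws a uniform random 3-D rotation, applies it to the left
hemisphere's parcel centroids, applies the x-mirrored rotation to the
right hemisphere, and re-labels each parcel with the nearest rotated
same-hemisphere parcel. Because the reassignment is nearest-neighbour,
rows are not bijections: some parcels appear twice, others drop out, as
in the standard centroid-based spin test. p-values use the plus-one
permutation convention and are therefore never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import split_rng
from .containers import ParcellationGeometry

__all__ = [
    "SpinEnsemble",
    "make_spin_ensemble",
    "spin_pvalue",
    "null_statistics",
    "fdr_bh",
]


@dataclass
class SpinEnsemble:
    indices: np.ndarray  # (n_perms, n_parcels) int
    fingerprint: str
    seed: int
    include_identity: bool = False

    @property
    def n_perms(self) -> int:
        return self.indices.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.indices.shape[1]


def _uniform_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotations on SO(3) via normalized quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y**2 + z**2)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x**2 + z**2)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x**2 + y**2)
    return R

_MIRROR_X = np.diag([-1.0, 1.0, 1.0])


def make_spin_ensemble(
    geometry: ParcellationGeometry,
    n_perms: int = 10000,
    seed: int = 0,
    include_identity: bool = False,
) -> SpinEnsemble:
    """Index table of nearest-neighbour spin permutations.

    Row r gives, for every parcel position i, the source parcel whose
    rotated centroid lands closest to position i (same hemisphere), so a
    spun map is ``map[indices[r]]``. Rotations act on each hemisphere's
    own full spherical projection (so the hemisphere is closed under
    rotation); the left-hemisphere rotation is mirrored for the right
    hemisphere, which by the mirror symmetry of the projection yields the
    same index pattern on mirrored geometries.
    """
    left = geometry.hemi_indices("L")
    right = geometry.hemi_indices("R")
    if left.size == 0 or right.size == 0:
        raise ValueError("spin nulls require centroids in both hemispheres")
    rng = split_rng(seed, "spin")
    rotations = _uniform_rotations(n_perms, rng)
    indices = np.empty((n_perms + int(include_identity), geometry.n_parcels), dtype=np.intp)
    row0 = 0
    if include_identity:
        indices[0] = np.arange(geometry.n_parcels)
        row0 = 1
    from .synthgen import hemi_projection

    pl = hemi_projection(geometry.centroids[left])
    # mirror the right hemisphere into the left half before projecting;
    # the mirrored rotation in the original frame is then plain R here
    pr = hemi_projection(geometry.centroids[right] @ _MIRROR_X)
    for r in range(n_perms):
        R = rotations[r]
        # nearest rotated source for each original position (max dot
        # product = min great-circle distance on the unit sphere)
        src_l = np.argmax(pl @ (pl @ R.T).T, axis=1)
        src_r = np.argmax(pr @ (pr @ R.T).T, axis=1)
        row = np.empty(geometry.n_parcels, dtype=np.intp)
        row[left] = left[src_l]
        row[right] = right[src_r]
        indices[row0 + r] = row
    return SpinEnsemble(indices, geometry.fingerprint(), seed, include_identity)


def _rank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def _pearson_rows(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between each row of A and the vector b."""
    A = A - A.mean(axis=1, keepdims=True)
    b = b - b.mean()
    denom = np.sqrt((A**2).sum(axis=1) * (b**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (A @ b) / denom


def null_statistics(
    map_a: np.ndarray, map_b: np.ndarray, ensemble: SpinEnsemble,
    statistic: str = "spearman",
) -> tuple:
    """Observed statistic and its spin-null distribution (map_a spun)."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.size != ensemble.n_parcels or b.size != ensemble.n_parcels:
        raise ValueError("maps do not match the ensemble's parcellation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map: correlation undefined")
    spun = a[ensemble.indices]
    if statistic == "spearman":
        observed = float(stats.spearmanr(a, b).statistic)
        nulls = _pearson_rows(_rank(spun, axis=1), _rank(b))
    elif statistic == "pearson":
        observed = float(stats.pearsonr(a, b).statistic)
        nulls = _pearson_rows(spun, b)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return observed, nulls


def spin_pvalue(
    map_a, map_b, ensemble: SpinEnsemble, statistic: str = "spearman"
) -> tuple:
    """Two-sided spin-test p-value, plus-one convention.

    p = (1 + #{|null| >= |observed|}) / (1 + n_perms); identity rows (if
    the ensemble was built with one) are excluded from the null.
    """
    observed, nulls = null_statistics(map_a, map_b, ensemble, statistic)
    if ensemble.include_identity:
        nulls = nulls[1:]
    nulls = nulls[np.isfinite(nulls)]
    n = nulls.size
    p = (1.0 + np.sum(np.abs(nulls) >= abs(observed))) / (1.0 + n)
    return observed, float(p)


def fdr_bh(p_values, q: float = 0.05) -> tuple:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(reject_mask, adjusted_p)``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adj
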