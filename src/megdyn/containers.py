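"""Core in-memory containers shared across the pipeline.

All brain maps are vectors over parcels of a :class:`ParcellationGeometry`;
feature extraction produces :class:`FeatureMatrix` objects (parcels x
features with a validity mask); spectral model fits and multivariate
results get their own light dataclasses in their home modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParcellationGeometry",
    "RegionalTimeSeriesSet",
    "FeatureMatrix",
    "SyntheticGroundTruth",
]


@dataclass
class ParcellationGeometry:
    """Parcel centroids on the unit sphere with hemisphere labels.

    Attributes
    ----------
    centroids : (n_parcels, 3) float array, each row unit-norm.
    hemisphere : (n_parcels,) array of 'L' / 'R'.
    parcel_ids : ordered list of parcel labels.
    """

    centroids: np.ndarray
    hemisphere: np.ndarray
    parcel_ids: list

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        if self.centroids.ndim != 2 or self.centroids.shape[1] != 3:
            raise ValueError("centroids must be (n_parcels, 3)")
        norms = np.linalg.norm(self.centroids, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(f"centroid {bad} is not unit-norm (|c|={norms[bad]:.12f})")
        labels = set(self.hemisphere.tolist())
        if not labels <= {"L", "R"}:
            raise ValueError(f"hemisphere labels must be 'L'/'R', got {labels}")
        if len(self.parcel_ids) != self.n_parcels:
            raise ValueError("parcel_ids length mismatch")

    @property
    def n_parcels(self) -> int:
        return self.centroids.shape[0]

    def hemi_indices(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    def fingerprint(self) -> str:
        """Stable digest of the geometry, used to tag derived artefacts."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(np.round(self.centroids, 12)).tobytes())
        h.update("".join(map(str, self.hemisphere.tolist())).encode())
        return h.hexdigest()[:16]


@dataclass
class RegionalTimeSeriesSet:
    """Per-participant regional time-series (participants x regions x samples)."""

    data: np.ndarray
    fs: float
    participant_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:  # single participant
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError("data must be (participants, regions, samples)")
        if not self.participant_ids:
            self.participant_ids = [f"sub-{i:02d}" for i in range(self.n_participants)]

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class FeatureMatrix:
    """Parcels x features table with validity mask and normalization state.

    ``values`` and ``mask`` are aligned DataFrames (index = parcel ids,
    columns = feature names). Entries with ``mask == False`` are failed or
    undefined computations and are excluded from every statistic.
    """

    values: pd.DataFrame
    mask: pd.DataFrame = None
    normalization: str = "raw"
    participant: str = "group"

    def __post_init__(self):
        if self.mask is None:
            self.mask = pd.DataFrame(
                np.isfinite(self.values.to_numpy(dtype=float)),
                index=self.values.index,
                columns=self.values.columns,
            )
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dup}")
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")
        if self.normalization not in ("raw", "sigmoid-scaled"):
            raise ValueError(f"unknown normalization state {self.normalization!r}")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list:
        return list(self.values.columns)

    def valid_values(self, feature: str) -> np.ndarray:
        col = self.values[feature].to_numpy(dtype=float)
        return col[self.mask[feature].to_numpy(dtype=bool)]

    def masked(self) -> np.ndarray:
        """Values with invalid entries as NaN."""
        v = self.values.to_numpy(dtype=float).copy()
        v[~self.mask.to_numpy(dtype=bool)] = np.nan
        return v

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(), self.mask.copy(), self.normalization, self.participant
        )


@dataclass
class SyntheticGroundTruth:
    """Ground truth stored alongside generated datasets for recovery tests."""

    latent_map: np.ndarray
    ts_weights: np.ndarray = None
    micro_weights: np.ndarray = None
    noise_sd: float = 0.0
    seed: int = 0
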