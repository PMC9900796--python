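"""Readers and writers for the pipeline's on-disk formats.

Everything tabular is TSV; time-series sets use a single-file NumPy
archive (.npz); every dataset gets a JSON sidecar with seeds and
parameters. Readers validate schema invariants (unit-norm centroids,
unique feature names, flagged missing values) and fail with the offending
row or column named.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, ParcellationGeometry, RegionalTimeSeriesSet

__all__ = [
    "write_geometry", "read_geometry",
    "write_map", "read_map",
    "write_feature_matrix", "read_feature_matrix",
    "write_timeseries", "read_timeseries",
    "write_manifest", "read_manifest",
]


class SchemaError(ValueError):
    pass


def write_geometry(geometry: ParcellationGeometry, path) -> None:
    df = pd.DataFrame(
        {
            "parcel_id": geometry.parcel_ids,
            "hemisphere": geometry.hemisphere,
            "x": geometry.centroids[:, 0],
            "y": geometry.centroids[:, 1],
            "z": geometry.centroids[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.15g")


def read_geometry(path) -> ParcellationGeometry:
    df = pd.read_csv(path, sep="\t")
    need = {"parcel_id", "hemisphere", "x", "y", "z"}
    if not need <= set(df.columns):
        raise SchemaError(f"geometry file missing columns {need - set(df.columns)}")
    cent = df[["x", "y", "z"]].to_numpy(dtype=float)
    norms = np.linalg.norm(cent, axis=1)
    bad = np.flatnonzero(np.abs(norms - 1.0) > 1e-6)
    if bad.size:
        raise SchemaError(f"non-unit centroid at row {int(bad[0])} (|c|={norms[bad[0]]:.9f})")
    cent /= norms[:, None]  # tidy rounding from the text round-trip
    return ParcellationGeometry(cent, df["hemisphere"].to_numpy(object),
                                df["parcel_id"].astype(str).tolist())


def write_map(values, parcel_ids, path, name: str = "value") -> None:
    pd.DataFrame({"parcel_id": parcel_ids, name: np.asarray(values, dtype=float)}).to_csv(
        path, sep="\t", index=False, float_format="%.15g"
    )


def read_map(path, name: str = "value"):
    df = pd.read_csv(path, sep="\t")
    if name not in df.columns:
        raise SchemaError(f"map file lacks column {name!r}")
    return df[name].to_numpy(dtype=float), df["parcel_id"].astype(str).tolist()


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    """TSV of values plus a companion .mask.tsv of validity flags."""
    path = Path(path)
    fm.values.to_csv(path, sep="\t", float_format="%.15g")
    fm.mask.astype(int).to_csv(path.with_suffix(path.suffix + ".mask.tsv"), sep="\t")


def read_feature_matrix(path, normalization: str = "raw",
                        participant: str = "group") -> FeatureMatrix:
    path = Path(path)
    # pandas de-duplicates repeated header names on read: check them raw
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dup = next(h for h in header if header.count(h) > 1)
        raise SchemaError(f"duplicated feature name {dup!r}")
    values = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    mask_path = path.with_suffix(path.suffix + ".mask.tsv")
    if mask_path.exists():
        mask = pd.read_csv(mask_path, sep="\t", index_col=0).astype(bool)
    else:
        mask = None
    if mask is not None:
        unflagged = (~np.isfinite(values.to_numpy(dtype=float))) & mask.to_numpy()
        if unflagged.any():
            i, j = np.argwhere(unflagged)[0]
            raise SchemaError(
                f"missing value not flagged invalid at ({values.index[i]}, {values.columns[j]})"
            )
    return FeatureMatrix(values, mask, normalization, participant)


def write_timeseries(ts: RegionalTimeSeriesSet, path, meta: dict = None) -> None:
    path = Path(path)
    np.savez_compressed(path, data=ts.data, fs=ts.fs,
                        participant_ids=np.array(ts.participant_ids, dtype=object))
    if meta is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(meta, indent=2, default=_jsonable))


def read_timeseries(path) -> RegionalTimeSeriesSet:
    with np.load(Path(path).with_suffix(".npz"), allow_pickle=True) as z:
        return RegionalTimeSeriesSet(
            data=z["data"], fs=float(z["fs"]),
            participant_ids=list(z["participant_ids"]),
        )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_jsonable))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
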