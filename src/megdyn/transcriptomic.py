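"""Microarray expression processing (multi-donor, probe-level).

The pipeline mirrors the standard regional-expression workflow: probes
below background intensity in at least half of the pooled samples are
discarded; when several probes index one gene the probe with the highest
differential stability

    DS(p) = mean over donor pairs of Spearman rho between the probe's
            regional profiles in the two donors

is kept; expression is normalized with a robust sigmoid + unit rescale,
first across genes within each sample, then across samples within each
gene; samples (mirrored bilaterally) are assigned to the nearest parcel
centroid within a distance threshold, averaged within donor then across
donors, and parcels left empty are filled by inverse-distance weighting
over all samples. Cell-class maps are unweighted means over gene sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ParcellationGeometry
from .synthgen import DonorExpressionSet
from .tsfeat import robust_sigmoid

__all__ = [
    "probe_intensity_filter",
    "differential_stability",
    "differential_stability_select",
    "normalize_expression",
    "assign_samples_to_parcels",
    "build_regional_expression",
    "celltype_expression_maps",
    "default_max_dist",
]


def probe_intensity_filter(dset: DonorExpressionSet, threshold: float = 0.5) -> list:
    """Probes retained by the background-intensity rule.

    A probe is discarded when the fraction of samples (pooled across
    donors) in which it lies below background is >= ``threshold``.
    """
    flags = pd.concat([dset.above_background[d] for d in dset.donors], axis=1)
    n_samples = flags.shape[1]
    retained = []
    for probe in flags.index:
        row = flags.loc[probe]
        if n_samples == 0:
            warnings.warn(f"probe {probe} has no samples; discarded")
            continue
        below_frac = 1.0 - row.mean()
        if below_frac < threshold:
            retained.append(probe)
    return retained


def _regional_profiles(dset: DonorExpressionSet, assignment: dict) -> dict:
    """Per-donor probe x region mean expression over assigned samples."""
    profiles = {}
    for d in dset.donors:
        expr = dset.expression[d]
        parc = np.asarray(assignment[d])
        regions = {}
        for r in np.unique(parc[parc >= 0]):
            cols = expr.columns[parc == r]
            regions[int(r)] = expr[cols].mean(axis=1)
        profiles[d] = pd.DataFrame(regions)
    return profiles


def differential_stability(dset: DonorExpressionSet, assignment: dict,
                           probes: list = None) -> pd.Series:
    """DS per probe: mean pairwise Spearman rho of regional profiles."""
    if len(dset.donors) < 2:
        raise ValueError("need at least two donors")
    profiles = _regional_profiles(dset, assignment)
    donors = dset.donors
    if probes is None:
        probes = dset.probes
    ds = pd.Series(np.nan, index=probes, name="DS")
    pair_corrs = {p: [] for p in probes}
    for i in range(len(donors) - 1):
        for j in range(i + 1, len(donors)):
            a, b = profiles[donors[i]], profiles[donors[j]]
            common = [c for c in a.columns if c in set(b.columns)]
            if len(common) < 3:
                continue
            av = a[common].loc[probes].to_numpy(dtype=float)
            bv = b[common].loc[probes].to_numpy(dtype=float)
            ra = stats.rankdata(av, axis=1)
            rb = stats.rankdata(bv, axis=1)
            ra = ra - ra.mean(axis=1, keepdims=True)
            rb = rb - rb.mean(axis=1, keepdims=True)
            denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                rho = (ra * rb).sum(axis=1) / denom
            for p, r in zip(probes, rho):
                if np.isfinite(r):
                    pair_corrs[p].append(float(r))
    for p in probes:
        if pair_corrs[p]:
            ds[p] = float(np.mean(pair_corrs[p]))
    return ds


def differential_stability_select(dset: DonorExpressionSet, assignment: dict,
                                  probes: list = None):
    """One probe per gene: the probe with maximal DS.

    Returns ``(selected: Series gene -> probe, ds: Series per probe)``.
    Genes whose probes all lack a DS value are dropped with a warning.
    """
    ds = differential_stability(dset, assignment, probes=probes)
    genes = dset.probe_genes.loc[ds.index]
    selected = {}
    for gene, group in ds.groupby(genes):
        group = group.dropna()
        if group.empty:
            warnings.warn(f"gene {gene} has no scorable probe; dropped")
            continue
        selected[gene] = group.idxmax()
    return pd.Series(selected, name="probe"), ds


def normalize_expression(values: pd.DataFrame) -> pd.DataFrame:
    """Two-stage robust-sigmoid + unit-rescale normalization.

    ``values`` is genes x samples for one donor. Stage 1 normalizes each
    sample across genes; stage 2 normalizes each gene across samples. The
    bare IQR is used (no Gaussian-consistency factor). Degenerate axes
    (zero IQR) become NaN.
    """
    out = values.astype(float).copy()
    # across genes within each sample
    for c in out.columns:
        scaled, ok = robust_sigmoid(out[c].to_numpy(), iqr_norm=1.0)
        out[c] = scaled if ok else np.nan
    # across samples within each gene
    arr = out.to_numpy()
    for i in range(arr.shape[0]):
        row = arr[i]
        if not np.all(np.isfinite(row)):
            arr[i] = np.nan
            continue
        scaled, ok = robust_sigmoid(row, iqr_norm=1.0)
        arr[i] = scaled if ok else np.nan
    return pd.DataFrame(arr, index=values.index, columns=values.columns)


def default_max_dist(geometry: ParcellationGeometry, scale_mm: float) -> float:
    """Half the median nearest-neighbour centroid spacing, in mm units.

    The areal 2 mm assignment radius of voxel-based atlases has no direct
    analogue for point centroids; this default preserves its role (assign
    nearby samples, exclude distant ones) at centroid resolution.
    """
    pts = geometry.centroids * scale_mm
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)) / 2.0)


def assign_samples_to_parcels(
    sample_coords: np.ndarray,
    geometry: ParcellationGeometry,
    scale_mm: float = 100.0,
    max_dist: float = None,
    mirror: bool = True,
):
    """Nearest-centroid assignment of tissue samples (optionally mirrored).

    Returns ``(assignment, mirrored_assignment)``: per-sample parcel index
    or -1 when the sample is farther than ``max_dist`` from every
    centroid. With ``mirror=True`` the x-reflected copy of each sample is
    assigned too (so each sample can contribute bilaterally).
    """
    coords = np.asarray(sample_coords, dtype=float)
    pts = geometry.centroids * scale_mm
    if max_dist is None:
        max_dist = default_max_dist(geometry, scale_mm)

    def nearest(c):
        d = np.linalg.norm(pts[None, :, :] - c[:, None, :], axis=-1)
        idx = np.argmin(d, axis=1)
        best = d[np.arange(len(c)), idx]
        idx[best > max_dist] = -1
        return idx

    assignment = nearest(coords)
    mirrored = None
    if mirror:
        mirrored = nearest(coords * np.array([-1.0, 1.0, 1.0]))
    return assignment, mirrored


def build_regional_expression(
    dset: DonorExpressionSet,
    geometry: ParcellationGeometry,
    max_dist: float = None,
    mirror: bool = True,
    background_threshold: float = 0.5,
):
    """Full probe-to-parcel processing chain.

    probe filter -> DS probe selection -> per-donor two-stage
    normalization -> sample assignment (with mirroring) -> donor-wise then
    cross-donor averaging -> inverse-distance fill of empty parcels.
    Returns ``(parcels x genes DataFrame in [0,1], provenance dict)``.
    """
    retained = probe_intensity_filter(dset, threshold=background_threshold)
    if not retained:
        raise RuntimeError("no probe survived the intensity filter")
    # DS needs a region assignment: use the same nearest-centroid rule
    assignment = {}
    for d in dset.donors:
        a, m = assign_samples_to_parcels(
            dset.sample_coords[d], geometry, scale_mm=dset.scale_mm,
            max_dist=max_dist, mirror=False,
        )
        assignment[d] = a
    selected, ds = differential_stability_select(dset, assignment, probes=retained)
    genes = list(selected.index)
    probes = list(selected.values)

    n_parc = geometry.n_parcels
    donor_maps = []
    all_samples_vals = []   # pooled normalized samples for the distance fill
    all_samples_pts = []
    for d in dset.donors:
        expr = dset.expression[d].loc[probes]
        expr.index = genes
        norm = normalize_expression(expr)
        a, m = assign_samples_to_parcels(
            dset.sample_coords[d], geometry, scale_mm=dset.scale_mm,
            max_dist=max_dist, mirror=mirror,
        )
        acc = np.zeros((n_parc, len(genes)))
        cnt = np.zeros(n_parc)
        vals = norm.to_numpy(dtype=float).T  # samples x genes
        for s in range(vals.shape[0]):
            for parc in {a[s], (m[s] if m is not None else -1)}:
                if parc >= 0 and np.all(np.isfinite(vals[s])):
                    acc[parc] += vals[s]
                    cnt[parc] += 1
        donor_map = np.full((n_parc, len(genes)), np.nan)
        has = cnt > 0
        donor_map[has] = acc[has] / cnt[has, None]
        donor_maps.append(donor_map)
        keepers = np.all(np.isfinite(vals), axis=1)
        all_samples_vals.append(vals[keepers])
        pts = np.asarray(dset.sample_coords[d], dtype=float)[keepers]
        all_samples_pts.append(pts)
        if mirror:
            all_samples_vals.append(vals[keepers])
            all_samples_pts.append(pts * np.array([-1.0, 1.0, 1.0]))

    stack = np.stack(donor_maps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        group = np.nanmean(stack, axis=0)
    empty = ~np.isfinite(group).all(axis=1)
    if empty.any():
        sv = np.vstack(all_samples_vals)
        sp = np.vstack(all_samples_pts)
        centroids_mm = geometry.centroids * dset.scale_mm
        for parc in np.flatnonzero(empty):
            d = np.linalg.norm(sp - centroids_mm[parc], axis=1)
            w = 1.0 / np.maximum(d, 1e-9)
            group[parc] = (w[:, None] * sv).sum(axis=0) / w.sum()
    out = pd.DataFrame(group, index=geometry.parcel_ids, columns=genes)
    provenance = {"selected_probes": selected, "differential_stability": ds,
                  "n_probes_retained": len(retained), "empty_parcels_filled": int(empty.sum())}
    return out, provenance


def celltype_expression_maps(expr: pd.DataFrame, gene_sets: dict) -> pd.DataFrame:
    """Unweighted mean expression per cell class over its gene set."""
    cols = {}
    for klass, genes in gene_sets.items():
        present = [g for g in genes if g in expr.columns]
        missing = sorted(set(genes) - set(present))
        if missing:
            warnings.warn(f"class {klass}: {len(missing)} genes missing, dropped")
        if not present:
            raise ValueError(f"cell class {klass} matched no genes")
        cols[klass] = expr[present].mean(axis=1)
    return pd.DataFrame(cols, index=expr.index)
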