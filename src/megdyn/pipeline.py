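"""Configuration-driven orchestration of the full analysis.

Stages: simulate -> spectral -> features -> gradient -> pls -> confounds
-> expression (optional). Each stage writes TSV tables into the run
directory and registers itself in a JSON manifest carrying the config
digest, seeds, and output checksums, so outputs from different configs
cannot be silently mixed. Downstream stages fail with a named dependency
error if an upstream stage was toggled off.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import confounds as cf
from . import gradients as gr
from . import io as mio
from . import plsmap as pls
from . import spatialnulls as sn
from . import spectral as sp
from . import synthgen as sg
from . import transcriptomic as tx
from . import tsfeat as tf
from ._rng import split_rng

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

STAGES = ("simulate", "spectral", "features", "gradient", "pls", "confounds", "expression")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results/run"
    stages: tuple = STAGES[:6]          # expression off by default
    # synthetic cohort
    n_per_hemisphere: int = 50
    n_participants: int = 6
    duration_s: float = 110.0           # 30 s dropped + 80 s analyzed
    fs_hz: float = 509.0
    latent_lengthscale: float = 0.8
    participant_jitter: float = 0.05
    # spectrum gradient: knee and peak amplitude ride the latent map
    # (latent is z-scored, so slopes leave a margin at |latent| ~ 3)
    knee_base: float = 250.0
    knee_slope: float = 70.0
    exponent_base: float = 2.0
    exponent_slope: float = 0.0
    peak_center: float = 10.0
    peak_center_slope: float = 1.5
    peak_height: float = 2e-3
    peak_height_slope: float = 0.6e-3
    peak_width: float = 1.5
    # micro-architecture bank
    n_micro_maps: int = 45
    micro_coupling: float = 0.7
    # analysis settings
    drop_initial_s: float = 30.0
    analyze_s: float = 80.0
    n_perms: int = 1000
    n_boot: int = 500
    n_splits: int = 99
    iqr_norm: float = 1.35
    # expression stage
    n_donors: int = 6
    n_probes: int = 120
    expression_reliability: float = 0.8
    # SNR model
    n_sensors: int = 64

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw["stages"] = tuple(raw.get("stages", STAGES[:6]))
        return cls(**raw)


def _require(results: dict, stage: str, needed_by: str):
    if stage not in results:
        raise PipelineError(f"stage '{needed_by}' requires '{stage}' which did not run")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a dict of in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    manifest = {"config_digest": config.digest(), "seed": config.seed, "stages": {}}
    results: dict = {}

    def log_stage(name, t0, files):
        manifest["stages"][name] = {
            "wall_s": round(time.time() - t0, 2),
            "files": sorted(str(f.relative_to(out)) for f in files),
        }

    if "simulate" in config.stages:
        t0 = time.time()
        geometry = sg.gen_parcellation(config.n_per_hemisphere, seed=config.seed)
        latent = sg.gen_smooth_map(geometry, config.latent_lengthscale, config.seed,
                                   stream="pipeline_latent")
        profile = sg.AperiodicProfile(
            offset=0.0, knee=config.knee_base, exponent=config.exponent_base,
            knee_slope=config.knee_slope, exponent_slope=config.exponent_slope,
        )
        peaks = (
            sg.PeakSpec(config.peak_center, config.peak_height, config.peak_width,
                        center_slope=config.peak_center_slope,
                        height_slope=config.peak_height_slope),
        )
        ts = sg.gen_regional_timeseries(
            geometry, config.duration_s, config.fs_hz,
            aperiodic_profile=profile, peak_profile=peaks, seed=config.seed,
            latent_map=latent, n_participants=config.n_participants,
            participant_jitter=config.participant_jitter,
        )
        noise_ts = sg.gen_empty_room(
            geometry, config.duration_s, config.fs_hz, seed=config.seed,
            n_participants=config.n_participants,
        )
        micro = sg.gen_micro_maps(geometry, latent, n_maps=config.n_micro_maps,
                                  coupling=config.micro_coupling, seed=config.seed)
        mio.write_geometry(geometry, out / "geometry.tsv")
        mio.write_map(latent, geometry.parcel_ids, out / "latent_map.tsv", name="latent")
        micro.to_csv(out / "micro_maps.tsv", sep="\t")
        results["simulate"] = {
            "geometry": geometry, "latent": latent, "ts": ts,
            "noise_ts": noise_ts, "micro": micro, "profile": profile, "peaks": peaks,
        }
        log_stage("simulate", t0, [out / "geometry.tsv", out / "latent_map.tsv",
                                   out / "micro_maps.tsv"])

    if "spectral" in config.stages:
        _require(results, "simulate", "spectral")
        t0 = time.time()
        sim = results["simulate"]
        ts = sim["ts"]
        geometry = sim["geometry"]
        band_maps = {}
        tau_maps = []
        fits_all = []
        for s in range(ts.n_participants):
            psd = sp.welch_psd(ts, participant=s)
            bp = sp.band_power(psd, sp.TOTAL_POWER_BANDS)
            for name, vals in bp.items():
                band_maps.setdefault(name, []).append(vals)
            fits = sp.fit_spectra(psd)
            fits_all.append(fits)
            tau_maps.append([sp.knee_frequency_and_timescale(f)[1] for f in fits])
        band_group = {name: np.mean(v, axis=0) for name, v in band_maps.items()}
        tau_group = np.nanmedian(np.asarray(tau_maps, dtype=float), axis=0)
        osc = sp.oscillation_score(fits_all, sp.ADJUSTED_BANDS)
        band_df = pd.DataFrame(band_group, index=geometry.parcel_ids)
        band_df["timescale_s"] = tau_group
        for name, m in osc.items():
            band_df[f"osc_score_{name}"] = m.score
        band_df.to_csv(out / "spectral_maps.tsv", sep="\t")
        results["spectral"] = {"band_maps": band_group, "timescale": tau_group,
                               "oscillation": osc, "fits": fits_all}
        log_stage("spectral", t0, [out / "spectral_maps.tsv"])

    if "features" in config.stages:
        _require(results, "simulate", "features")
        t0 = time.time()
        sim = results["simulate"]
        group, per_sub = tf.extract_group_features(
            sim["ts"], parcel_ids=sim["geometry"].parcel_ids,
            iqr_norm=config.iqr_norm,
            drop_initial_s=config.drop_initial_s, analyze_s=config.analyze_s,
        )
        noise_group, _ = tf.extract_group_features(
            sim["noise_ts"], parcel_ids=sim["geometry"].parcel_ids,
            iqr_norm=config.iqr_norm,
            drop_initial_s=config.drop_initial_s, analyze_s=config.analyze_s,
        )
        mio.write_feature_matrix(group, out / "features_group.tsv")
        mio.write_feature_matrix(noise_group, out / "features_noise_group.tsv")
        results["features"] = {"group": group, "per_sub": per_sub,
                               "noise_group": noise_group}
        log_stage("features", t0, [out / "features_group.tsv",
                                   out / "features_noise_group.tsv"])

    ensemble = None

    def get_ensemble():
        nonlocal ensemble
        if ensemble is None:
            _require(results, "simulate", "spin ensemble")
            ensemble = sn.make_spin_ensemble(
                results["simulate"]["geometry"], n_perms=config.n_perms,
                seed=config.seed,
            )
        return ensemble

    if "gradient" in config.stages:
        _require(results, "features", "gradient")
        t0 = time.time()
        sim = results["simulate"]
        group = results["features"]["group"]
        pca = gr.fit_pca(group, reference_map=sim["latent"])
        loadings = gr.component_loadings(group, pca, component=1,
                                         ensemble=get_ensemble())
        comparisons = None
        if "spectral" in results:
            fam = dict(results["spectral"]["band_maps"])
            tau = results["spectral"]["timescale"]
            if np.all(np.isfinite(tau)):
                fam["timescale"] = tau
            comparisons = gr.correlate_map_family(pca.score_map(1), fam, get_ensemble())
            comparisons.to_csv(out / "pc1_map_comparisons.tsv", sep="\t")
        mio.write_map(pca.score_map(1), sim["geometry"].parcel_ids,
                      out / "pc1_scores.tsv", name="pc1")
        loadings.to_csv(out / "pc1_loadings.tsv", sep="\t")
        results["gradient"] = {"pca": pca, "loadings": loadings,
                               "comparisons": comparisons}
        log_stage("gradient", t0, [out / "pc1_scores.tsv", out / "pc1_loadings.tsv"])

    if "pls" in config.stages:
        _require(results, "features", "pls")
        _require(results, "simulate", "pls")
        t0 = time.time()
        sim = results["simulate"]
        X = results["features"]["group"]
        Y = sim["micro"]
        fit = pls.pls_fit(X, Y)
        fit.p_spin = pls.pls_permutation_test(X, Y, get_ensemble())
        x_ci, y_ci = pls.pls_bootstrap_loadings(X, Y, n_boot=config.n_boot,
                                                seed=config.seed)
        fit.x_loading_ci, fit.y_loading_ci = x_ci, y_ci
        cv = pls.distance_dependent_cv(
            X, Y, sim["geometry"],
            n_splits=min(config.n_splits, sim["geometry"].n_parcels),
            seed=config.seed,
        )
        summary = pd.DataFrame({
            "lv": np.arange(1, fit.n_lv + 1),
            "singular_value": fit.S,
            "effect_size": fit.effect_sizes,
            "p_spin": fit.p_spin,
        })
        summary.to_csv(out / "pls_lvs.tsv", sep="\t", index=False)
        cv.to_csv(out / "pls_cv.tsv", sep="\t", index=False)
        pd.DataFrame({
            "parcel_id": sim["geometry"].parcel_ids,
            "x_score_lv1": fit.x_scores[:, 0],
            "y_score_lv1": fit.y_scores[:, 0],
        }).to_csv(out / "pls_scores.tsv", sep="\t", index=False)
        results["pls"] = {"fit": fit, "cv": cv}
        log_stage("pls", t0, [out / "pls_lvs.tsv", out / "pls_cv.tsv",
                              out / "pls_scores.tsv"])

    if "confounds" in config.stages:
        _require(results, "features", "confounds")
        _require(results, "simulate", "confounds")
        t0 = time.time()
        sim = results["simulate"]
        geometry = sim["geometry"]
        rng = split_rng(config.seed, "snr_model")
        base_gain = rng.lognormal(0.0, 0.3, size=config.n_sensors)
        noise_var = rng.lognormal(0.0, 0.3, size=config.n_sensors) ** 2
        depth = sg.gen_smooth_map(geometry, config.latent_lengthscale,
                                  config.seed, stream="snr_depth")
        snr_map = np.array([
            cf.snr_db(cf.SensorModel(gains=base_gain * np.exp(0.3 * depth[r]),
                                     noise_var=noise_var))
            for r in range(geometry.n_parcels)
        ])
        group = results["features"]["group"]
        retained, report = cf.snr_feature_filter(group, snr_map, get_ensemble())
        pca_full = gr.fit_pca(group, reference_map=sim["latent"])
        filtered_pca = None
        if retained.n_features >= 2:
            filtered_pca = gr.fit_pca(retained, reference_map=sim["latent"])
        residual = cf.regress_covariate(group, snr_map)
        res_ok = residual.values.loc[:, residual.values.std() > 1e-12]
        regressed_pca = gr.fit_pca(res_ok, reference_map=sim["latent"])
        noise_r, noise_p, _ = cf.noise_component_comparison(
            group, results["features"]["noise_group"], get_ensemble(),
        )
        mio.write_map(snr_map, geometry.parcel_ids, out / "snr_map.tsv", name="snr_db")
        report.to_csv(out / "snr_filter_report.tsv", sep="\t")
        results["confounds"] = {
            "snr_map": snr_map, "filter_report": report,
            "pca_full": pca_full, "pca_filtered": filtered_pca,
            "pca_regressed": regressed_pca,
            "noise_comparison": (noise_r, noise_p),
        }
        log_stage("confounds", t0, [out / "snr_map.tsv", out / "snr_filter_report.tsv"])

    if "expression" in config.stages:
        _require(results, "simulate", "expression")
        t0 = time.time()
        sim = results["simulate"]
        dset, _ = sg.gen_donor_expression(
            config.n_donors, sim["geometry"].n_parcels, config.n_probes,
            config.expression_reliability, config.seed, geometry=sim["geometry"],
        )
        expr, prov = tx.build_regional_expression(dset, sim["geometry"])
        genes = list(expr.columns)
        third = max(1, len(genes) // 3)
        gene_sets = {"class_a": genes[:third], "class_b": genes[third:2 * third],
                     "class_c": genes[2 * third:]}
        cellmaps = tx.celltype_expression_maps(expr, gene_sets)
        expr.to_csv(out / "expression_regional.tsv", sep="\t")
        cellmaps.to_csv(out / "expression_celltypes.tsv", sep="\t")
        results["expression"] = {"regional": expr, "celltypes": cellmaps,
                                 "provenance": prov}
        log_stage("expression", t0, [out / "expression_regional.tsv",
                                     out / "expression_celltypes.tsv"])

    mio.write_manifest(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results
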