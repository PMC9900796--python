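"""Expression processing: probe filter, differential stability, assignment."""

import numpy as np
import pandas as pd
import pytest

from megdyn.synthgen import DonorExpressionSet, gen_donor_expression, gen_parcellation
from megdyn.transcriptomic import (
    assign_samples_to_parcels,
    build_regional_expression,
    celltype_expression_maps,
    default_max_dist,
    differential_stability,
    differential_stability_select,
    normalize_expression,
    probe_intensity_filter,
)


def _toy_dset(profiles: dict, probe_genes=None, coords=None, regions=None):
    """Donor -> probes x regions values; one sample per region, at centroids."""
    donors = list(profiles)
    n_probes, n_regions = np.asarray(profiles[donors[0]]).shape
    probes = [f"p{i}" for i in range(n_probes)]
    geom = gen_parcellation(max(2, n_regions // 2), seed=0)
    expression, above, sc, sr = {}, {}, {}, {}
    for d in donors:
        vals = np.asarray(profiles[d], dtype=float)
        cols = [f"{d}_s{j}" for j in range(n_regions)]
        expression[d] = pd.DataFrame(vals, index=probes, columns=cols)
        above[d] = pd.DataFrame(True, index=probes, columns=cols)
        sc[d] = geom.centroids[:n_regions] * 100.0
        sr[d] = np.arange(n_regions)
    pg = probe_genes if probe_genes is not None else pd.Series(
        [f"g{i}" for i in range(n_probes)], index=probes
    )
    return DonorExpressionSet(expression, above, sc, sr, pg), geom


class TestProbeFilter:
    def _dset_with_flags(self, frac_below):
        n = 100
        probes = ["p0"]
        cols = [f"s{j}" for j in range(n)]
        expr = pd.DataFrame(np.ones((1, n)), index=probes, columns=cols)
        flags = np.ones(n, dtype=bool)
        flags[: int(round(frac_below * n))] = False
        above = pd.DataFrame(flags[None, :], index=probes, columns=cols)
        return DonorExpressionSet({"d0": expr}, {"d0": above},
                                  {"d0": np.zeros((n, 3))}, {"d0": np.zeros(n)},
                                  pd.Series(["g0"], index=probes))

    @pytest.mark.parametrize("frac,kept", [(0.0, True), (0.49, True),
                                           (0.50, False), (0.51, False)])
    def test_threshold_sides(self, frac, kept):
        dset = self._dset_with_flags(frac)
        retained = probe_intensity_filter(dset)
        assert (len(retained) == 1) is kept


class TestDifferentialStability:
    def test_identical_profiles(self):
        prof = np.array([[1.0, 2.0, 3.0, 4.0]])
        dset, _ = _toy_dset({"d0": prof, "d1": prof})
        ds = differential_stability(dset, {"d0": np.arange(4), "d1": np.arange(4)})
        assert ds["p0"] == pytest.approx(1.0)

    def test_reversed_profiles(self):
        dset, _ = _toy_dset({"d0": [[1.0, 2.0, 3.0, 4.0]],
                             "d1": [[4.0, 3.0, 2.0, 1.0]]})
        ds = differential_stability(dset, {"d0": np.arange(4), "d1": np.arange(4)})
        assert ds["p0"] == pytest.approx(-1.0)

    def test_three_donor_pairwise_mean(self):
        # donors A = B = [1,2,3]; C = [2,1,3]: rho(A,B)=1, rho(A,C)=rho(B,C)=0.5
        dset, _ = _toy_dset({"d0": [[1.0, 2.0, 3.0]],
                             "d1": [[1.0, 2.0, 3.0]],
                             "d2": [[2.0, 1.0, 3.0]]})
        assignment = {d: np.arange(3) for d in ("d0", "d1", "d2")}
        ds = differential_stability(dset, assignment)
        assert ds["p0"] == pytest.approx(2.0 / 3.0)

    def test_best_probe_selected_per_gene(self):
        stable = [1.0, 2.0, 3.0, 4.0]
        noisy_a = [2.0, 1.0, 4.0, 3.0]
        noisy_b = [4.0, 3.0, 1.0, 2.0]
        dset, _ = _toy_dset(
            {"d0": [stable, noisy_a], "d1": [stable, noisy_b]},
            probe_genes=pd.Series(["gene", "gene"], index=["p0", "p1"]),
        )
        sel, ds = differential_stability_select(
            dset, {"d0": np.arange(4), "d1": np.arange(4)}
        )
        assert sel["gene"] == "p0"
        assert ds["p0"] > ds["p1"]

    def test_reliability_monotone(self):
        meds = []
        for rel in (0.0, 0.3, 0.6, 0.9, 1.0):
            dset, _ = gen_donor_expression(4, 30, 200, rel, seed=60, coverage=1.0)
            assignment = {d: dset.sample_region[d] for d in dset.donors}
            meds.append(differential_stability(dset, assignment).median())
        assert all(b > a - 1e-9 for a, b in zip(meds[:-1], meds[1:]))


class TestNormalization:
    def test_two_stage_endpoints(self):
        rng = np.random.default_rng(70)
        df = pd.DataFrame(rng.lognormal(0, 1, (11, 7)),
                          index=[f"g{i}" for i in range(11)],
                          columns=[f"s{j}" for j in range(7)])
        out = normalize_expression(df)
        arr = out.to_numpy()
        assert np.nanmin(arr) >= 0.0 and np.nanmax(arr) <= 1.0
        # stage 2 normalizes rows: each gene spans exactly [0, 1]
        np.testing.assert_allclose(np.nanmin(arr, axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(np.nanmax(arr, axis=1), 1.0, atol=1e-12)

    def test_formula_oracle_single_sample(self):
        x = np.array([0.0, 1.0, 2.0, 10.0])
        med = np.median(x)
        iqr = np.quantile(x, 0.75) - np.quantile(x, 0.25)
        norm = 1.0 / (1.0 + np.exp(-(x - med) / iqr))
        expect = (norm - norm.min()) / (norm.max() - norm.min())
        df = pd.DataFrame({"s0": x}, index=[f"g{i}" for i in range(4)])
        from megdyn.tsfeat import robust_sigmoid

        got, ok = robust_sigmoid(x, iqr_norm=1.0)
        assert ok
        np.testing.assert_allclose(got, expect, rtol=1e-12)

    def test_not_idempotent(self):
        # the two-stage scheme is order-dependent, not a projection
        rng = np.random.default_rng(71)
        df = pd.DataFrame(rng.lognormal(0, 1, (9, 6)))
        df.columns = [f"s{j}" for j in range(6)]
        once = normalize_expression(df)
        twice = normalize_expression(once)
        assert not np.allclose(once.to_numpy(), twice.to_numpy())


class TestAssignment:
    def test_sample_at_centroid_assigned(self, geometry):
        coords = geometry.centroids[[3, 17]] * 100.0
        a, _ = assign_samples_to_parcels(coords, geometry, scale_mm=100.0,
                                         mirror=False)
        np.testing.assert_array_equal(a, [3, 17])

    def test_distant_sample_excluded(self, geometry):
        coords = np.array([[500.0, 500.0, 500.0]])
        a, _ = assign_samples_to_parcels(coords, geometry, scale_mm=100.0,
                                         mirror=False)
        assert a[0] == -1

    def test_mirroring_targets_mirror_parcel(self, geometry):
        left = geometry.hemi_indices("L")[0]
        coords = geometry.centroids[[left]] * 100.0
        a, m = assign_samples_to_parcels(coords, geometry, scale_mm=100.0,
                                         mirror=True)
        assert a[0] == left
        mirror_centroid = geometry.centroids[m[0]]
        np.testing.assert_allclose(
            mirror_centroid, geometry.centroids[left] * [-1, 1, 1], atol=1e-9
        )

    def test_default_max_dist_positive(self, geometry):
        assert default_max_dist(geometry, 100.0) > 0


class TestRegionalExpression:
    def test_end_to_end_values_in_unit_interval(self):
        dset, geom = gen_donor_expression(4, 40, 60, 0.9, seed=80, coverage=0.8)
        expr, prov = build_regional_expression(dset, geom)
        arr = expr.to_numpy()
        assert arr.shape[0] == geom.n_parcels
        assert np.all(np.isfinite(arr))
        assert arr.min() >= 0.0 and arr.max() <= 1.0
        assert prov["n_probes_retained"] > 0

    def test_celltype_maps(self):
        idx = [f"r{i}" for i in range(5)]
        expr = pd.DataFrame({
            "g0": [0.1, 0.2, 0.3, 0.4, 0.5],
            "g1": [0.5, 0.4, 0.3, 0.2, 0.1],
            "g2": [0.0, 0.0, 1.0, 1.0, 0.0],
        }, index=idx)
        maps = celltype_expression_maps(expr, {"single": ["g0"],
                                               "pair": ["g0", "g1"],
                                               "trio": ["g0", "g1", "g2"]})
        np.testing.assert_allclose(maps["single"], expr["g0"])
        np.testing.assert_allclose(maps["pair"], (expr["g0"] + expr["g1"]) / 2)
        # loop oracle
        acc = np.zeros(5)
        for g in ("g0", "g1", "g2"):
            acc += expr[g].to_numpy()
        np.testing.assert_allclose(maps["trio"], acc / 3)

    def test_empty_class_rejected(self):
        expr = pd.DataFrame({"g0": [0.1, 0.2]})
        with pytest.raises(ValueError):
            celltype_expression_maps(expr, {"none": ["missing_gene"]})
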