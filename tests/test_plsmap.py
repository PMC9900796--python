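"""PLS decomposition, permutation inference, bootstrap, and distance CV."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from megdyn.plsmap import (
    distance_dependent_cv,
    pls_bootstrap_loadings,
    pls_fit,
    pls_permutation_test,
)
from megdyn.spatialnulls import make_spin_ensemble
from megdyn.synthgen import gen_coupled_feature_sets, gen_smooth_map


def _df(arr, prefix):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestFit:
    def test_shared_structure_single_lv(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(50)
        X = _df(np.column_stack([z, 2 * z]), "x")
        Y = _df(np.column_stack([z, -z]), "y")
        fit = pls_fit(X, Y)
        assert fit.effect_sizes[0] == pytest.approx(1.0, abs=1e-9)
        r = np.corrcoef(fit.x_scores[:, 0], fit.y_scores[:, 0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_columns_zero_singular_values(self):
        # columns mutually orthogonal over parcels after centering
        n = 8
        H = np.linalg.qr(np.random.default_rng(1).standard_normal((n, n)))[0]
        # drop the near-constant direction, keep orthogonal columns
        cols = H[:, :4]
        cols = cols - cols.mean(0)
        Q = np.linalg.qr(cols)[0]
        X = _df(Q[:, :2], "x")
        Y = _df(Q[:, 2:4], "y")
        fit = pls_fit(X, Y)
        assert np.all(np.abs(fit.S) < 1e-9)

    def test_2x2_brute_force_svd_oracle(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [0.0, 1.0]])
        Y = np.array([[1.0, 0.0], [0.0, 2.0], [4.0, 1.0], [2.0, 2.0]])
        Zx = (X - X.mean(0)) / X.std(0, ddof=1)
        Zy = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        R = Zx.T @ Zy / 3.0  # hand-computed 2x2 cross-correlation
        s_oracle = np.linalg.svd(R, compute_uv=False)
        fit = pls_fit(_df(X, "x"), _df(Y, "y"))
        np.testing.assert_allclose(fit.S, s_oracle, atol=1e-12)

    def test_effect_sizes_sum_to_one_and_orthonormal(self):
        rng = np.random.default_rng(2)
        fit = pls_fit(_df(rng.standard_normal((40, 6)), "x"),
                      _df(rng.standard_normal((40, 4)), "y"))
        assert fit.effect_sizes.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(fit.S) <= 1e-12)
        np.testing.assert_allclose(fit.U.T @ fit.U, np.eye(fit.n_lv), atol=1e-10)
        np.testing.assert_allclose(fit.V.T @ fit.V, np.eye(fit.n_lv), atol=1e-10)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 5))
        Y = rng.standard_normal((30, 4))
        a = pls_fit(_df(X, "x"), _df(Y, "y"))
        perm = rng.permutation(5)
        b = pls_fit(_df(X[:, perm], "x"), _df(Y, "y"))
        np.testing.assert_allclose(a.S, b.S, atol=1e-10)
        np.testing.assert_allclose(np.abs(a.U[perm, 0]), np.abs(b.U[:, 0]), atol=1e-8)

    def test_matches_sklearn_plssvd(self):
        from sklearn.cross_decomposition import PLSSVD

        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 4))
        fit = pls_fit(_df(X, "x"), _df(Y, "y"))
        sk = PLSSVD(n_components=4, scale=True).fit(X, Y)
        for j in range(4):
            cu = abs(np.corrcoef(fit.U[:, j], sk.x_weights_[:, j])[0, 1])
            cv = abs(np.corrcoef(fit.V[:, j], sk.y_weights_[:, j])[0, 1])
            assert cu == pytest.approx(1.0, abs=1e-8)
            assert cv == pytest.approx(1.0, abs=1e-8)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 3))
        X[:, 1] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            fit = pls_fit(_df(X, "x"), _df(rng.standard_normal((20, 3)), "y"))
        assert len(fit.x_names) == 2


class TestPermutation:
    def test_identity_row_reproduces_observed(self, geometry):
        X, Y, _ = gen_coupled_feature_sets(geometry, 6, 4, 0.8, 0.3, seed=8)
        ens = make_spin_ensemble(geometry, n_perms=3, seed=1, include_identity=True)
        from megdyn.plsmap import _svd_cross, _zscore_drop_constant

        Zx, _ = _zscore_drop_constant(X.values, "x")
        Zy, _ = _zscore_drop_constant(Y, "y")
        _, s_obs, _ = _svd_cross(Zx, Zy, 4)
        Zp = Zx[ens.indices[0]]
        _, s_id, _ = _svd_cross(Zp, Zy, 4)
        np.testing.assert_allclose(s_id, s_obs, atol=1e-12)

    def test_perfect_coupling_minimal_p(self, geometry):
        X, Y, _ = gen_coupled_feature_sets(geometry, 8, 5, 1.0, 0.0, seed=9)
        ens = make_spin_ensemble(geometry, n_perms=200, seed=2)
        p = pls_permutation_test(X, Y, ens)
        # observed beats every null except spins so small that the
        # nearest-neighbour reassignment collapses to the identity
        n_id = int(np.sum((ens.indices == np.arange(ens.n_parcels)).all(axis=1)))
        assert p[0] == pytest.approx((1.0 + n_id) / 201.0)
        assert p[0] <= 3.0 / 201.0

    def test_geometry_mismatch_rejected(self, geometry):
        from megdyn.synthgen import gen_parcellation

        X, Y, _ = gen_coupled_feature_sets(geometry, 5, 4, 0.5, 0.2, seed=10)
        small = gen_parcellation(10, seed=0)
        ens = make_spin_ensemble(small, n_perms=10, seed=0)
        with pytest.raises(ValueError):
            pls_permutation_test(X, Y, ens)


class TestBootstrap:
    def test_zero_noise_ci_width_zero(self, geometry):
        X, Y, _ = gen_coupled_feature_sets(geometry, 5, 4, 1.0, 0.0, seed=11)
        x_ci, y_ci = pls_bootstrap_loadings(X, Y, n_boot=50, seed=3)
        # deterministic rank-1 relation: LV1 loadings do not vary
        width = x_ci[1][:, 0] - x_ci[0][:, 0]
        assert np.all(np.abs(width) < 1e-9)

    def test_ci_bounds_ordered_around_point(self, geometry):
        X, Y, _ = gen_coupled_feature_sets(geometry, 6, 4, 0.8, 0.5, seed=12)
        fit = pls_fit(X, Y)
        x_ci, y_ci = pls_bootstrap_loadings(X, Y, n_boot=200, seed=4)
        lo, hi = x_ci
        assert np.all(lo <= hi + 1e-12)
        inside = (lo[:, 0] <= fit.x_loadings[:, 0] + 0.05) & (
            fit.x_loadings[:, 0] <= hi[:, 0] + 0.05
        )
        assert inside.mean() >= 0.99


class TestDistanceCV:
    def test_split_sizes(self, geometry):
        X, Y, _ = gen_coupled_feature_sets(geometry, 5, 4, 0.9, 0.3, seed=13)
        cv = distance_dependent_cv(X, Y, geometry, n_splits=10, seed=5)
        assert len(cv) == 10
        # 100 parcels -> 75 train / 25 test per split by construction
        from megdyn.plsmap import _as_frame

        n = _as_frame(X, "x").shape[0]
        assert int(round(0.75 * n)) == 75

    def test_shared_columns_perfect_test_correlation(self, geometry):
        rng = np.random.default_rng(6)
        z = rng.standard_normal(geometry.n_parcels)
        w = rng.standard_normal(geometry.n_parcels)
        X = _df(np.column_stack([z, w]), "x")
        Y = _df(np.column_stack([z, w]), "y")
        cv = distance_dependent_cv(X, Y, geometry, n_splits=20, seed=7)
        np.testing.assert_allclose(cv["test_r"], 1.0, atol=1e-9)

    def test_test_not_better_than_train_under_noise(self, geometry):
        X, Y, _ = gen_coupled_feature_sets(geometry, 10, 6, 0.7, 0.8, seed=14)
        cv = distance_dependent_cv(X, Y, geometry, n_splits=99, seed=8)
        assert cv["test_r"].mean() <= cv["train_r"].mean() + 1e-9

    def test_too_many_splits_rejected(self, geometry):
        X, Y, _ = gen_coupled_feature_sets(geometry, 4, 4, 0.5, 0.3, seed=15)
        with pytest.raises(ValueError):
            distance_dependent_cv(X, Y, geometry, n_splits=101, seed=0)


class TestRecovery:
    def test_weight_recovery_under_noise_quick(self, geometry):
        """Reduced version of the parameter-recovery experiment."""
        rs = []
        for rep in range(5):
            X, Y, truth = gen_coupled_feature_sets(
                geometry, 10, 6, 0.9, 0.5, seed=300 + rep
            )
            fit = pls_fit(X, Y)
            rs.append(abs(np.corrcoef(fit.U[:, 0], truth.ts_weights)[0, 1]))
        assert np.median(rs) > 0.9
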