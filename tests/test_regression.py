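from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from arealepi.regression import (
    GWR,
    REPORT_COLUMNS,
    REPORT_SUMMARY_ROWS,
    SpatialOLS,
    compare_models,
    screen_variables,
)
from arealepi.synthetic import SyntheticConfig, generate_dataset
from arealepi.weights import queen_weights
from oracles import normal_equations_ols


def random_problem(seed, n=60, k=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, k))
    beta = rng.normal(size=k + 1)
    y = beta[0] + X @ beta[1:] + rng.normal(0, 0.5, n)
    return X, y


class TestOLS:
    def test_exact_linear_data_interpolated(self):
        x = np.arange(10.0)
        y = 2.0 + 3.0 * x
        fit = SpatialOLS().fit(x[:, None], y)
        assert fit.params_ == pytest.approx([2.0, 3.0], abs=1e-10)
        assert fit.ssr_ == pytest.approx(0.0, abs=1e-18)
        assert fit.r2_ == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_normal_equations_oracle(self, seed):
        X, y = random_problem(seed)
        fit = SpatialOLS().fit(X, y)
        beta, bse, t, ssr = normal_equations_ols(X, y)
        assert np.allclose(fit.params_, beta, atol=1e-10)
        assert np.allclose(fit.bse_, bse, atol=1e-10)
        assert np.allclose(fit.tvalues_, t, atol=1e-10)
        assert fit.ssr_ == pytest.approx(ssr, abs=1e-9)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        X, y = random_problem(7)
        fit = SpatialOLS().fit(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(fit.params_, ref.params, atol=1e-10)
        assert np.allclose(fit.bse_, ref.bse, atol=1e-10)
        assert np.allclose(fit.pvalues_, ref.pvalues, atol=1e-10)
        assert fit.adj_r2_ == pytest.approx(ref.rsquared_adj, abs=1e-10)

    def test_aic_convention_documented_formula(self):
        X, y = random_problem(3, n=50, k=2)
        fit = SpatialOLS().fit(X, y)
        n, k = 50, 2
        expected = n * np.log(fit.ssr_ / n) + n * np.log(2 * np.pi) + n + 2 * (k + 2)
        assert fit.aic_ == pytest.approx(expected)

    def test_rank_deficiency_names_collinear_column(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=40)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=40)})
        y = rng.normal(size=40)
        with pytest.raises(ValueError, match="rank deficient"):
            SpatialOLS().fit(X, y)

    def test_type_one_error_rate_near_nominal(self):
        # pure-noise regressions: |t| > 1.96 should fire at ~5%
        hits, total = 0, 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(80, 2))
            y = rng.normal(size=80)
            fit = SpatialOLS().fit(X, y)
            hits += int((np.abs(fit.tvalues_[1:]) > 1.96).sum())
            total += 2
        assert 0.01 <= hits / total <= 0.12

    def test_residual_moran_computed_with_weights(self, small_dataset):
        w = queen_weights(small_dataset.areas, mode="row_standardized")
        y = small_dataset.areas.deaths.to_numpy(float)
        X = small_dataset.areas[["tpr", "ipdm"]]
        fit = SpatialOLS(weights=w, permutations=99, seed=0).fit(X, y)
        assert fit.residual_moran_ is not None
        assert np.isfinite(fit.residual_moran_.I_)


class TestScreening:
    def _fit_with_t(self, tvals):
        names = ["Constant"] + [f"v{i}" for i in range(len(tvals))]
        return SimpleNamespace(coef_names_=names, tvalues_=np.array([9.9] + list(tvals)))

    def test_all_pass_published_magnitudes(self):
        fit = self._fit_with_t([11.27, -2.60, 4.78, -2.12])
        assert screen_variables(fit) == ["v0", "v1", "v2", "v3"]

    def test_none_pass_below_threshold(self):
        assert screen_variables(self._fit_with_t([1.0, -1.5])) == []

    def test_boundary_value_excluded(self):
        assert screen_variables(self._fit_with_t([1.96, -1.961])) == ["v1"]


class TestGWR:
    def test_global_uniform_limit_reproduces_ols(self, small_dataset):
        ds = small_dataset
        y = ds.areas.deaths.to_numpy(float)
        X = ds.areas[["tpr", "ipdm"]]
        coords = np.array([[g.centroid.x, g.centroid.y] for g in ds.areas.geometry])
        ols = SpatialOLS().fit(X, y)
        gwr = GWR(kernel="uniform", bandwidth=len(ds.areas) - 1).fit(X, y, coords)
        assert np.abs(gwr.local_coef_ - ols.params_).max() < 1e-8

    def test_kernel_weights_bounded_and_local(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 100, size=(30, 2))
        from scipy.spatial.distance import cdist

        d = cdist(coords, coords)
        Wk = GWR(kernel="adaptive_bisquare")._kernel_weights(d, 8)
        assert Wk.min() >= 0 and Wk.max() <= 1
        assert np.allclose(np.diag(Wk), 1.0)
        # beyond the 8th-nearest distance the weight is exactly zero
        b = np.sort(d, axis=1)[:, 8]
        assert (Wk[d > b[:, None]] == 0).all()

    def test_effective_params_between_p_and_n(self, small_dataset):
        ds = small_dataset
        y = ds.areas.deaths.to_numpy(float)
        X = ds.areas[["tpr", "ipdm"]]
        coords = np.array([[g.centroid.x, g.centroid.y] for g in ds.areas.geometry])
        gwr = GWR().fit(X, y, coords)
        assert 3 <= gwr.tr_S_ <= len(ds.areas)

    def test_unknown_kernel_and_bandwidth_rejected(self, small_dataset):
        ds = small_dataset
        y = ds.areas.deaths.to_numpy(float)
        X = ds.areas[["tpr"]]
        coords = np.array([[g.centroid.x, g.centroid.y] for g in ds.areas.geometry])
        with pytest.raises(ValueError, match="kernel"):
            GWR(kernel="triangular", bandwidth=10).fit(X, y, coords)
        with pytest.raises(ValueError, match="bandwidth"):
            GWR(bandwidth="BIC").fit(X, y, coords)


class TestModelComparison:
    def test_global_limit_verdict_is_global(self, small_dataset):
        ds = small_dataset
        w = queen_weights(ds.areas, mode="row_standardized")
        y = ds.areas.deaths.to_numpy(float)
        X = ds.areas[["tpr", "ipdm"]]
        coords = np.array([[g.centroid.x, g.centroid.y] for g in ds.areas.geometry])
        ols = SpatialOLS(weights=w, permutations=99, seed=0).fit(X, y)
        gwr = GWR(kernel="uniform", bandwidth=len(ds.areas) - 1, weights=w,
                  permutations=99, seed=0).fit(X, y, coords)
        report = compare_models(ols, gwr)
        assert report.verdict == "global"

    def test_report_has_published_table_shape(self, small_dataset):
        ds = small_dataset
        w = queen_weights(ds.areas, mode="row_standardized")
        y = ds.areas.deaths.to_numpy(float)
        X = ds.areas[["tpr", "ipdm"]]
        coords = np.array([[g.centroid.x, g.centroid.y] for g in ds.areas.geometry])
        ols = SpatialOLS(weights=w, permutations=99, seed=0).fit(X, y)
        gwr = GWR(weights=w, permutations=99, seed=0).fit(X, y, coords)
        report = compare_models(ols, gwr)
        assert list(report.coefficients.columns) == REPORT_COLUMNS
        assert list(report.summary.index) == REPORT_SUMMARY_ROWS
        assert list(report.summary.columns) == ["OLS", "GWR"]

    def test_mismatched_data_rejected(self, small_dataset):
        ds = small_dataset
        y = ds.areas.deaths.to_numpy(float)
        X = ds.areas[["tpr", "ipdm"]]
        coords = np.array([[g.centroid.x, g.centroid.y] for g in ds.areas.geometry])
        ols = SpatialOLS().fit(X, y)
        gwr = GWR(kernel="uniform", bandwidth=len(ds.areas) - 1).fit(
            X, y + 1.0, coords
        )
        with pytest.raises(ValueError, match="identical"):
            compare_models(ols, gwr)
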