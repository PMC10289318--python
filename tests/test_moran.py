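import itertools

import numpy as np
import pytest

from arealepi.moran import LocalMoran, Moran, global_moran, local_moran
from arealepi.synthetic import SyntheticConfig, generate_tessellation, regular_grid
from arealepi.weights import SpatialWeights, queen_weights, spatial_lag
from oracles import naive_local_moran, naive_moran


def rook_2x2():
    ids = ["a", "b", "c", "d"]  # row-major 2x2
    nbrs = {"a": ["b", "c"], "b": ["a", "d"], "c": ["a", "d"], "d": ["b", "c"]}
    return SpatialWeights(nbrs, mode="binary", ids=ids)


class TestGlobalMoran:
    def test_checkerboard_on_2x2_rook_is_minus_one(self):
        m = Moran(weights=rook_2x2(), permutations=9, seed=0).fit(
            np.array([1.0, -1.0, -1.0, 1.0])
        )
        assert m.I_ == pytest.approx(-1.0, abs=1e-14)

    def test_expected_value_is_minus_one_over_n_minus_one(self, grid33):
        _, w = grid33
        m = global_moran(np.arange(9.0), w.to_mode("row_standardized"), n_perm=99, seed=0)
        assert m.expected_I_ == pytest.approx(-1.0 / 8)

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_exhaustive_permutation_mean(self, n, rng):
        # mean of I over all n! relabellings equals -1/(n-1)
        geoms = regular_grid(n, 1)
        w = queen_weights(geoms, mode="row_standardized")
        x = rng.normal(size=n)
        z = x - x.mean()
        W, s0 = w.matrix, w.s0
        vals = [
            n / s0 * (z[list(p)] @ (W @ z[list(p)])) / (z @ z)
            for p in itertools.permutations(range(n))
        ]
        assert np.mean(vals) == pytest.approx(-1.0 / (n - 1), abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        geoms = generate_tessellation(SyntheticConfig(n_units=40, seed=8))
        for mode in ("binary", "row_standardized"):
            w = queen_weights(geoms, mode=mode)
            x = rng.normal(size=w.n)
            m = Moran(weights=w, permutations=9, seed=0).fit(x)
            ref = naive_moran(x, w.neighbors, w.ids, row_standardize=(mode != "binary"))
            assert m.I_ == pytest.approx(ref, abs=1e-10)

    def test_permutation_p_reproducible_and_bounded(self, grid33, rng):
        _, wb = grid33
        w = wb.to_mode("row_standardized")
        x = rng.normal(size=9)
        a = Moran(weights=w, permutations=999, seed=7).fit(x)
        b = Moran(weights=w, permutations=999, seed=7).fit(x)
        assert a.p_sim_ == b.p_sim_
        assert np.array_equal(a.sims_, b.sims_)
        assert a.p_sim_ >= 1.0 / 1000

    def test_constant_surface_rejected(self, grid33):
        _, w = grid33
        with pytest.raises(ValueError, match="constant"):
            Moran(weights=w, permutations=9, seed=0).fit(np.ones(9))

    def test_islands_excluded_from_statistic(self):
        ids = ["a", "b", "c", "d"]
        nbrs = {"a": ["b"], "b": ["a", "c"], "c": ["b"], "d": []}
        w = SpatialWeights(nbrs, mode="row_standardized", ids=ids)
        x = np.array([1.0, 2.0, 3.0, 99.0])
        m = Moran(weights=w, permutations=9, seed=0).fit(x)
        assert m.n_ == 3
        assert m.expected_I_ == pytest.approx(-0.5)


class TestLocalMoran:
    def test_local_sum_identity_with_row_standardized_weights(self, rng):
        geoms = generate_tessellation(SyntheticConfig(n_units=45, seed=2))
        w = queen_weights(geoms, mode="row_standardized")
        x = rng.normal(size=w.n)
        g = Moran(weights=w, permutations=9, seed=0).fit(x)
        l = LocalMoran(weights=w, permutations=9, seed=0).fit(x)
        assert l.Is_.sum() / w.n == pytest.approx(g.I_, abs=1e-10)

    def test_matches_double_loop_oracle(self, rng):
        geoms = generate_tessellation(SyntheticConfig(n_units=30, seed=6))
        w = queen_weights(geoms, mode="row_standardized")
        x = rng.normal(size=w.n)
        l = LocalMoran(weights=w, permutations=9, seed=0).fit(x)
        ref = naive_local_moran(x, w.neighbors, w.ids, row_standardize=True)
        assert np.allclose(l.Is_, ref, atol=1e-10)

    def test_embedded_high_block_becomes_hot_spot(self):
        # 8x8 grid, low background with a high 3x3 block in one corner:
        # the block core is HH; no HH unit outside the block's queen closure
        nx = ny = 8
        geoms = regular_grid(nx, ny)
        w = queen_weights(geoms, mode="row_standardized")
        x = np.zeros(nx * ny)
        block = [j * nx + i for j in range(3) for i in range(3)]
        x[block] = 10.0
        rngx = np.random.default_rng(1)
        x += rngx.normal(0, 0.01, nx * ny)  # break exact ties
        l = LocalMoran(weights=w, permutations=999, seed=3).fit(x)
        assert l.labels_[0] == "hot_spot"  # block corner, all-high neighborhood
        closure = set()
        for b in block:
            closure.add(geoms["unit_id"].iloc[b])
            closure.update(w.neighbors[geoms["unit_id"].iloc[b]])
        hh = {geoms["unit_id"].iloc[i] for i in np.flatnonzero(l.labels_ == "hot_spot")}
        assert hh <= closure
        far = [j * nx + i for j in range(5, 8) for i in range(5, 8)]
        assert set(l.labels_[far]) <= {"cold_spot", "not_significant"}

    def test_label_iff_pseudo_p_below_alpha(self, rng):
        geoms = generate_tessellation(SyntheticConfig(n_units=50, seed=12))
        w = queen_weights(geoms, mode="row_standardized")
        l = LocalMoran(weights=w, permutations=199, alpha=0.05, seed=0).fit(
            rng.normal(size=w.n)
        )
        sig = l.p_sim_ < 0.05
        assert np.array_equal(l.labels_ != "not_significant", sig)
        assert l.p_sim_.min() >= 1.0 / 200

    def test_quadrant_consistent_with_signs(self, rng):
        geoms = generate_tessellation(SyntheticConfig(n_units=40, seed=13))
        w = queen_weights(geoms, mode="row_standardized")
        x = rng.normal(size=w.n)
        l = LocalMoran(weights=w, permutations=99, seed=0).fit(x)
        z = x - x.mean()
        lag = spatial_lag(w, z)
        hh = l.quadrant_ == "HH"
        ll = l.quadrant_ == "LL"
        assert (z[hh] > 0).all() and (lag[hh] > 0).all()
        assert (z[ll] <= 0).all() and (lag[ll] <= 0).all()

    def test_island_gets_missing_statistic(self):
        ids = ["a", "b", "c", "d"]
        nbrs = {"a": ["b", "c"], "b": ["a", "c"], "c": ["a", "b"], "d": []}
        w = SpatialWeights(nbrs, mode="row_standardized", ids=ids)
        l = LocalMoran(weights=w, permutations=99, seed=0).fit(
            np.array([1.0, 2.0, 4.0, 8.0])
        )
        assert np.isnan(l.Is_[3])
        assert l.labels_[3] == "not_significant"

    def test_conditional_permutation_reproducible(self, grid33, rng):
        _, wb = grid33
        w = wb.to_mode("row_standardized")
        x = rng.normal(size=9)
        a = LocalMoran(weights=w, permutations=199, seed=11).fit(x)
        b = LocalMoran(weights=w, permutations=199, seed=11).fit(x)
        assert np.array_equal(a.p_sim_, b.p_sim_)
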