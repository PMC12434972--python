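"""Spatial weights, Moran statistics, LISA categories and Gi* hotspots."""

import numpy as np
import pytest

import pestspec as ps
from pestspec.spatial import DISTRIBUTION_MAP


def brute_force_global_moran(values, W_dense):
    """Literal double-sum recomputation of Moran's I."""
    v = np.asarray(values, float)
    z = v - v.mean()
    n = len(v)
    s0 = W_dense.sum()
    num = sum(
        W_dense[i, j] * z[i] * z[j] for i in range(n) for j in range(n)
    )
    return n / s0 * num / (z @ z)


def brute_force_local_moran(values, W_dense):
    v = np.asarray(values, float)
    z = v - v.mean()
    n = len(v)
    m2 = (z @ z) / n
    return np.array(
        [z[i] * sum(W_dense[i, j] * z[j] for j in range(n)) / m2 for i in range(n)]
    )


def rook_lattice_points(side):
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


class TestBuildWeights:
    def test_collinear_equidistant_knn1_tie_breaks_to_lowest_id(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        W = ps.build_weights(pts, scheme="knn", k=1)
        np.testing.assert_array_equal(W.neighbors[1], [0])

    def test_wide_distance_band_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, (12, 2))
        W = ps.build_weights(pts, scheme="distance_band", band=1000.0)
        assert all(len(nb) == 11 for nb in W.neighbors)

    def test_row_standardized_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 10, (20, 2))
        W = ps.build_weights(pts, scheme="knn", k=4, standardization="row")
        for w in W.weights:
            assert w.sum() == pytest.approx(1.0)

    def test_no_self_neighbors(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 5, (15, 2))
        W = ps.build_weights(pts, scheme="knn", k=3)
        for i, nb in enumerate(W.neighbors):
            assert i not in nb

    def test_distance_band_symmetric_before_standardization(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, (25, 2))
        W = ps.build_weights(pts, scheme="distance_band", band=3.0,
                             standardization="binary")
        D = W.dense()
        np.testing.assert_array_equal(D, D.T)

    def test_invalid_parameters_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            ps.build_weights(pts, scheme="knn", k=3)
        with pytest.raises(ValueError):
            ps.build_weights(pts, scheme="distance_band", band=0.1)
        with pytest.raises(ValueError):
            ps.build_weights(pts[:1], scheme="knn", k=1)


class TestGlobalMoran:
    def test_checkerboard_on_rook_lattice_is_minus_one(self):
        pts = rook_lattice_points(4)
        W = ps.build_weights(pts, scheme="distance_band", band=1.0)
        values = (pts.sum(axis=1) % 2) * 2.0 - 1.0  # +/-1 checkerboard
        res = ps.global_morans_i(values, W, permutations=99, seed=0)
        assert res.I == pytest.approx(-1.0, abs=1e-12)
        assert res.expected == pytest.approx(-1.0 / 15)

    def test_permutation_null_mean_matches_expectation(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 50, (100, 2))
        W = ps.build_weights(pts, scheme="knn", k=6)
        values = rng.permutation(np.repeat([1.0, 2.0, 3.0, 4.0], 25))
        sims = []
        for s in range(60):
            r = ps.global_morans_i(rng.permutation(values), W,
                                   permutations=99, seed=s)
            sims.append(r.I)
        se = np.std(sims, ddof=1) / np.sqrt(len(sims))
        assert abs(np.mean(sims) - (-1.0 / 99)) < 3 * se

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            pts = rng.uniform(0, 20, (30, 2))
            W = ps.build_weights(pts, scheme="knn", k=5)
            values = rng.normal(0, 1, 30)
            res = ps.global_morans_i(values, W, permutations=99, seed=trial)
            assert res.I == pytest.approx(
                brute_force_global_moran(values, W.dense()), abs=1e-12
            )

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 20, (40, 2))
        W = ps.build_weights(pts, scheme="knn", k=4)
        values = rng.normal(0, 1, 40)
        a = ps.global_morans_i(values, W, permutations=99, seed=1).I
        b = ps.global_morans_i(5.0 * values - 3.0, W, permutations=99, seed=1).I
        assert a == pytest.approx(b, abs=1e-12)

    def test_constant_values_rejected(self):
        pts = rook_lattice_points(3)
        W = ps.build_weights(pts, scheme="knn", k=2)
        with pytest.raises(ValueError):
            ps.global_morans_i(np.ones(9), W, permutations=99, seed=0)


class TestLocalMoran:
    def test_matches_brute_force_and_sums_to_global(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 30, (50, 2))
        W = ps.build_weights(pts, scheme="knn", k=6)
        values = rng.normal(0, 1, 50)
        res = ps.local_morans_i(values, W, permutations=99, seed=0)
        np.testing.assert_allclose(
            res.local_i, brute_force_local_moran(values, W.dense()), atol=1e-12
        )
        # row-standardized: sum_i I_i = S0 * I
        g = ps.global_morans_i(values, W, permutations=99, seed=0)
        assert res.local_i.sum() == pytest.approx(W.s0 * g.I, abs=1e-10)

    def test_single_high_outlier_among_low_neighbours_is_HL(self):
        # a severe tree whose neighbours are all healthy, in a stand that
        # elsewhere carries the full range of damage levels
        rng = np.random.default_rng(8)
        pts = rook_lattice_points(7) * 3.0
        values = rng.permutation(np.tile([1.0, 2.0, 3.0, 4.0], 13)[:49])
        W = ps.build_weights(pts, scheme="knn", k=4)
        values[24] = 4.0
        values[W.neighbors[24]] = 1.0
        res = ps.local_morans_i(values, W, permutations=999, alpha=0.05, seed=1)
        assert res.category[24] == "HL"
        assert res.p_sim[24] <= 0.05

    def test_planted_cluster_interior_is_HH(self):
        rng = np.random.default_rng(9)
        pts = rook_lattice_points(10) * 2.0
        values = rng.normal(1.0, 0.1, 100)
        cluster = [44, 45, 54, 55, 34, 35, 46, 56, 64, 65]
        values[cluster] = rng.normal(4.0, 0.1, len(cluster))
        W = ps.build_weights(pts, scheme="knn", k=8)
        res = ps.local_morans_i(values, W, permutations=999, alpha=0.05, seed=2)
        assert res.category[44] == "HH"
        assert res.category[55] == "HH"

    def test_null_field_mostly_not_significant(self):
        rng = np.random.default_rng(10)
        pts = rng.uniform(0, 40, (80, 2))
        W = ps.build_weights(pts, scheme="knn", k=6)
        values = rng.normal(0, 1, 80)
        res = ps.local_morans_i(values, W, permutations=199, alpha=0.01, seed=3)
        assert (res.category == "ns").mean() > 0.8
        types = ps.classify_distribution(res.category)
        assert set(types[res.category == "ns"]) == {"unclassified"}


class TestDistributionMapping:
    @pytest.mark.parametrize(
        "cat,expected",
        [("HH", "spread"), ("HL", "saltatory"), ("LH", "latent"),
         ("LL", "healthy"), ("ns", "unclassified")],
    )
    def test_fixed_category_mapping(self, cat, expected):
        assert ps.classify_distribution([cat])[0] == expected
        assert DISTRIBUTION_MAP[cat] == expected


class TestGiStar:
    def test_matches_direct_formula(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 20, (40, 2))
        W = ps.build_weights(pts, scheme="knn", k=5)
        x = rng.normal(2.0, 1.0, 40)
        res = ps.getis_ord_gi_star(x, W)
        n = 40
        xbar = x.mean()
        s = np.sqrt((x**2).mean() - xbar**2)
        for i in range(n):
            nb = W.neighbors[i]
            Wi = len(nb) + 1
            num = x[nb].sum() + x[i] - xbar * Wi
            den = s * np.sqrt((n * Wi - Wi**2) / (n - 1))
            assert res.z_scores[i] == pytest.approx(num / den, abs=1e-10)

    def test_planted_hot_core_peaks_inside(self):
        rng = np.random.default_rng(12)
        pts = rook_lattice_points(9) * 2.0
        x = rng.normal(1.0, 0.1, 81)
        core = [40, 39, 41, 31, 49, 30, 32, 48, 50]
        x[core] = rng.normal(4.0, 0.1, len(core))
        W = ps.build_weights(pts, scheme="knn", k=8)
        res = ps.getis_ord_gi_star(x, W)
        assert int(np.argmax(res.z_scores)) == 40
        assert res.hotspot_class[40] == "hot_p01"

    def test_null_calibration_of_significance_fraction(self):
        rng = np.random.default_rng(13)
        fracs = []
        for trial in range(30):
            pts = rng.uniform(0, 60, (100, 2))
            W = ps.build_weights(pts, scheme="knn", k=6)
            x = rng.normal(0, 1, 100)
            res = ps.getis_ord_gi_star(x, W)
            fracs.append(np.mean(np.abs(res.z_scores) > 1.959964))
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.05) < 3 * max(se, 0.005)

    def test_constant_values_rejected(self):
        pts = rook_lattice_points(3)
        W = ps.build_weights(pts, scheme="knn", k=2)
        with pytest.raises(ValueError):
            ps.getis_ord_gi_star(np.ones(9), W)


def test_analyze_spatial_bundles_everything(default_scene):
    trees = default_scene.trees
    res = ps.analyze_spatial(
        trees[["x", "y"]].to_numpy(),
        trees["damage_level"].to_numpy(float),
        permutations=199,
        seed=0,
    )
    assert res.global_moran.I > 0.5  # aggregated pattern is strongly clustered
    df = res.to_frame(index=trees["tree_id"])
    assert set(df.columns) >= {"local_i", "p_sim", "category", "gi_z",
                               "hotspot", "distribution_type"}
    assert len(df) == len(trees)
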