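import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hzkit import acoustics, genio, syngen
from hzkit.acoustics import PcaResult


def mc_overlap_oracle(points_a, points_b, n_points=100_000, seed=0):
    """Monte-Carlo mean-directed hull overlap, independent of shapely.

    Areas are estimated by uniform sampling over the joint bounding box
    with point-in-hull tests done by matplotlib's Path, so the polygon
    clipping route is never reused.
    """
    from matplotlib.path import Path as MplPath
    from scipy.spatial import ConvexHull

    rng = np.random.default_rng(seed)
    ha = ConvexHull(points_a)
    hb = ConvexHull(points_b)
    pa = MplPath(points_a[ha.vertices])
    pb = MplPath(points_b[hb.vertices])
    pts = np.vstack([points_a, points_b])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    sample = rng.uniform(lo, hi, size=(n_points, 2))
    in_a = pa.contains_points(sample)
    in_b = pb.contains_points(sample)
    na, nb, ni = in_a.sum(), in_b.sum(), (in_a & in_b).sum()
    if na == 0 or nb == 0:
        return 0.0
    return 0.5 * (ni / na + ni / nb)


def _pca_from_scores(scores, explained):
    scores = np.asarray(scores, dtype=float)
    scores = scores - scores.mean(axis=0)
    return PcaResult(
        scores=scores,
        explained=np.asarray(explained, dtype=float),
        loadings=np.eye(4),
        trait_names=("a", "b", "c", "d"),
    )


def _labels(sizes):
    out = []
    for g, s in zip(genio.CALL_GROUPS, sizes):
        out += [g] * s
    return np.array(out)


class TestTemperatureAdjust:
    def test_zero_slope_gives_centered_nd(self, null_calls):
        calls = null_calls
        flat = genio.CallTable(
            individuals=calls.individuals,
            localities=calls.localities,
            groups=calls.groups,
            temperature_c=calls.temperature_c,
            df_hz=calls.df_hz,
            nd_s=np.full(calls.n_individuals, 0.2) + 0,  # constant ND
            rt_s=np.full(calls.n_individuals, 0.05),
            pr_per_s=calls.pr_per_s,
        )
        adj = acoustics.temperature_adjust(flat)
        np.testing.assert_allclose(adj.traits[:, 1], 0.0, atol=1e-12)

    def test_residuals_orthogonal_to_temperature(self, null_calls):
        adj = acoustics.temperature_adjust(null_calls)
        r = np.corrcoef(null_calls.temperature_c, adj.traits[:, 1])[0, 1]
        assert abs(r) < 1e-10

    def test_planted_correlation_recovered(self, null_calls):
        # generator is calibrated to r(T, ND) ~ -0.64 at n = 71
        adj = acoustics.temperature_adjust(null_calls)
        assert adj.temperature_r == pytest.approx(-0.64, abs=0.15)

    def test_other_traits_untouched(self, null_calls):
        adj = acoustics.temperature_adjust(null_calls)
        np.testing.assert_array_equal(adj.traits[:, 0], null_calls.df_hz)
        np.testing.assert_array_equal(adj.traits[:, 2], null_calls.rt_s)
        np.testing.assert_array_equal(adj.traits[:, 3], null_calls.pr_per_s)

    def test_constant_temperature_is_an_error(self, null_calls):
        calls = null_calls
        frozen = genio.CallTable(
            individuals=calls.individuals, localities=calls.localities,
            groups=calls.groups, temperature_c=np.full(calls.n_individuals, 15.0),
            df_hz=calls.df_hz, nd_s=calls.nd_s, rt_s=calls.rt_s,
            pr_per_s=calls.pr_per_s,
        )
        with pytest.raises(ValueError, match="constant"):
            acoustics.temperature_adjust(frozen)


class TestRunPca:
    def test_explained_variances_sum_to_one(self, null_calls):
        pca = acoustics.run_pca(acoustics.temperature_adjust(null_calls))
        assert pca.explained.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(pca.explained >= 0)
        np.testing.assert_allclose(pca.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_independent_traits_split_variance_evenly(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((2000, 4))
        pca = acoustics.run_pca(x)
        np.testing.assert_allclose(pca.explained, 0.25, atol=0.04)

    def test_dominant_pair_loads_first_component(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal(500)
        x = np.column_stack([
            base + 0.1 * rng.standard_normal(500),
            base + 0.1 * rng.standard_normal(500),
            rng.standard_normal(500),
            rng.standard_normal(500),
        ])
        pca = acoustics.run_pca(x)
        assert pca.explained[0] > pca.explained[1]
        assert pca.explained[0] > 0.4

    def test_sign_convention(self, null_calls):
        pca = acoustics.run_pca(acoustics.temperature_adjust(null_calls))
        for j in range(4):
            dominant = np.argmax(np.abs(pca.loadings[:, j]))
            assert pca.loadings[dominant, j] > 0

    def test_constant_column_is_an_error(self):
        x = np.random.default_rng(0).standard_normal((50, 4))
        x[:, 2] = 1.0
        with pytest.raises(ValueError, match="constant"):
            acoustics.run_pca(x)

    def test_too_few_individuals_is_an_error(self):
        with pytest.raises(ValueError, match="at least 5"):
            acoustics.run_pca(np.zeros((3, 4)))


class TestHullOverlap:
    def test_identical_sets_give_one(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]], dtype=float)
        assert acoustics.hull_overlap_2d(pts, pts) == pytest.approx(1.0)

    def test_disjoint_hulls_give_zero(self):
        a = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        b = a + 10.0
        assert acoustics.hull_overlap_2d(a, b) == 0.0

    def test_half_shifted_unit_squares(self):
        # [0,1]^2 vs [0.5,1.5]x[0,1]: I = 0.5, both areas 1 -> 0.5
        a = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        b = a + [0.5, 0.0]
        assert acoustics.hull_overlap_2d(a, b) == pytest.approx(0.5, abs=1e-12)
        oracle = mc_overlap_oracle(a, b, seed=3)
        assert oracle == pytest.approx(0.5, abs=0.01)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((12, 2))
        b = rng.standard_normal((12, 2)) + 0.5
        assert acoustics.hull_overlap_2d(a, b) == pytest.approx(
            acoustics.hull_overlap_2d(b, a), rel=1e-12
        )

    @given(angle=st.floats(0, 2 * np.pi), dx=st.floats(-5, 5), dy=st.floats(-5, 5))
    @settings(max_examples=30, deadline=None)
    def test_rigid_motion_invariance(self, angle, dx, dy):
        rng = np.random.default_rng(17)
        a = rng.standard_normal((10, 2))
        b = rng.standard_normal((10, 2)) + 0.3
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        shift = np.array([dx, dy])
        before = acoustics.hull_overlap_2d(a, b)
        after = acoustics.hull_overlap_2d(a @ rot.T + shift, b @ rot.T + shift)
        assert after == pytest.approx(before, abs=1e-9)

    def test_degenerate_hull_warns_and_returns_zero(self):
        collinear = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        with pytest.warns(UserWarning, match="degenerate"):
            assert acoustics.hull_overlap_2d(collinear, square) == 0.0

    def test_too_few_points_is_an_error(self):
        a = np.array([[0, 0], [1, 0]], dtype=float)
        with pytest.raises(ValueError, match="3 points"):
            acoustics.hull_overlap_2d(a, a)

    def test_monte_carlo_oracle_agreement(self):
        # small version of the 50-pair acceptance check
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.standard_normal((10, 2))
            b = rng.standard_normal((10, 2)) + rng.uniform(-1, 1, 2)
            impl = acoustics.hull_overlap_2d(a, b)
            oracle = mc_overlap_oracle(a, b, seed=int(rng.integers(1 << 31)))
            assert impl == pytest.approx(oracle, abs=0.01)

    def test_jaccard_variant_bounded_by_directed_mean(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((10, 2))
        b = rng.standard_normal((10, 2)) + 0.3
        jac = acoustics.hull_overlap_jaccard(a, b)
        mean_dir = acoustics.hull_overlap_2d(a, b)
        assert 0 <= jac <= mean_dir <= 1


class TestStatistics:
    def test_same_distribution_overlap_near_one(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(-1, 1, (6000, 4))
        labels = _labels([1500, 1500, 1500, 1500])
        pca = _pca_from_scores(scores, [0.4, 0.3, 0.2, 0.1])
        assert acoustics.overlap_statistic(pca, labels, "allopatric") > 0.95

    def test_separated_clusters_give_zero_overlap(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((20, 4)) * 0.1
        b = a + 100.0
        scores = np.vstack([a, b, a, b])
        labels = _labels([20, 20, 20, 20])
        pca = _pca_from_scores(scores, [0.25, 0.25, 0.25, 0.25])
        assert acoustics.overlap_statistic(pca, labels, "parapatric") == 0.0

    def test_centroid_distance_zero_for_identical_means(self):
        rng = np.random.default_rng(7)
        block = rng.standard_normal((20, 4))
        scores = np.vstack([block, block, block, block])
        labels = _labels([20, 20, 20, 20])
        pca = _pca_from_scores(scores, [0.4, 0.3, 0.2, 0.1])
        assert acoustics.centroid_distance_statistic(pca, labels, "allopatric") == pytest.approx(0.0, abs=1e-12)

    def test_centroid_formula_reduction(self):
        # means differ by delta on PC1 only -> distance = v1 * delta
        delta, v1 = 3.0, 0.5
        a = np.zeros((10, 4))
        b = np.zeros((10, 4))
        b[:, 0] = delta
        scores = np.vstack([a, b, a, b])
        labels = _labels([10, 10, 10, 10])
        pca = _pca_from_scores(scores, [v1, 0.3, 0.1, 0.1])
        d = acoustics.centroid_distance_statistic(pca, labels, "allopatric")
        assert d == pytest.approx(v1 * delta, rel=1e-12)

    def test_centroid_translation_invariance(self):
        rng = np.random.default_rng(11)
        scores = rng.standard_normal((40, 4))
        labels = _labels([10, 10, 10, 10])
        pca1 = _pca_from_scores(scores, [0.4, 0.3, 0.2, 0.1])
        d1 = acoustics.centroid_distance_statistic(pca1, labels, "parapatric")
        pca2 = PcaResult(pca1.scores + 5.0, pca1.explained, pca1.loadings, pca1.trait_names)
        d2 = acoustics.centroid_distance_statistic(pca2, labels, "parapatric")
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_weighted_sd_zero_for_duplicated_points(self):
        scores = np.tile(np.array([[1.0, 2.0, 3.0, 4.0]]), (40, 1))
        labels = _labels([10, 10, 10, 10])
        pca = PcaResult(scores - scores.mean(0), np.array([0.4, 0.3, 0.2, 0.1]),
                        np.eye(4), ("a", "b", "c", "d"))
        assert acoustics.weighted_sd_statistic(pca, labels, "A", "allopatric") == 0.0

    def test_weighted_sd_homogeneity(self):
        rng = np.random.default_rng(13)
        scores = rng.standard_normal((40, 4))
        labels = _labels([10, 10, 10, 10])
        pca1 = _pca_from_scores(scores, [0.4, 0.3, 0.2, 0.1])
        pca2 = _pca_from_scores(scores * 2, [0.4, 0.3, 0.2, 0.1])
        s1 = acoustics.weighted_sd_statistic(pca1, labels, "B", "parapatric")
        s2 = acoustics.weighted_sd_statistic(pca2, labels, "B", "parapatric")
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_variance_reduction_halves_weighted_sd(self):
        # parapatric generated at rho = 0.5 of the allopatric SD, n = 500
        sc = syngen.CallScenario.variance_reduction(
            rho=0.5, group_sizes=(500, 500, 500, 500), seed=19
        )
        calls = syngen.simulate_calls(sc)
        pca = acoustics.run_pca(acoustics.temperature_adjust(calls))
        labels = np.array(calls.groups)
        for sp in ("A", "B"):
            s_allo = acoustics.weighted_sd_statistic(pca, labels, sp, "allopatric")
            s_para = acoustics.weighted_sd_statistic(pca, labels, sp, "parapatric")
            assert s_para / s_allo == pytest.approx(0.5, abs=0.08)

    def test_singleton_group_is_an_error(self):
        scores = np.random.default_rng(1).standard_normal((31, 4))
        labels = _labels([10, 10, 10, 1])
        pca = _pca_from_scores(scores, [0.25, 0.25, 0.25, 0.25])
        with pytest.raises(ValueError, match="fewer than 2"):
            acoustics.weighted_sd_statistic(pca, labels, "B", "parapatric")


class TestDeltaSuite:
    def test_cumulated_equals_sum_of_species_deltas(self, null_calls):
        pca = acoustics.run_pca(acoustics.temperature_adjust(null_calls))
        d = acoustics.delta_suite(pca, null_calls.groups)
        assert d["sd_cumulated"].delta == pytest.approx(
            d["sd_A"].delta + d["sd_B"].delta, rel=1e-12
        )

    def test_delta_sign_convention_para_minus_allo(self, null_calls):
        pca = acoustics.run_pca(acoustics.temperature_adjust(null_calls))
        d = acoustics.delta_suite(pca, null_calls.groups)
        for r in d.values():
            assert r.delta == pytest.approx(r.parapatric - r.allopatric, rel=1e-12)

    def test_missing_group_is_an_error(self, null_calls):
        pca = acoustics.run_pca(acoustics.temperature_adjust(null_calls))
        labels = np.array(null_calls.groups)
        labels[labels == genio.GROUP_PARA_B] = genio.GROUP_PARA_A
        with pytest.raises(ValueError, match="missing call groups"):
            acoustics.delta_suite(pca, labels)

    def test_variance_reduction_sign_pattern(self):
        # majority of seeds: smaller parapatric spread -> negative overlap
        # and cumulated-SD deltas
        hits_sd, hits_ov = 0, 0
        for seed in range(10):
            calls = syngen.simulate_calls(
                syngen.CallScenario.variance_reduction(rho=0.5, seed=seed)
            )
            pca = acoustics.run_pca(acoustics.temperature_adjust(calls))
            d = acoustics.delta_suite(pca, calls.groups)
            hits_sd += d["sd_cumulated"].delta < 0
            hits_ov += d["overlap"].delta < 0
        assert hits_sd >= 8
        assert hits_ov >= 8


class TestPermutationTest:
    def test_worked_pvalue_example(self):
        # exactly 22 of 1000 null draws at or beyond the observed value
        null = np.zeros(1000)
        null[:22] = 0.6  # |0.6| >= |0.49|
        assert acoustics.perm_pvalue(0.49, null) == 0.022
        assert acoustics.perm_pvalue(-0.49, null) == 0.022

    def test_zero_observed_gives_p_one(self):
        null = np.random.default_rng(0).standard_normal(100)
        assert acoustics.perm_pvalue(0.0, null) == 1.0

    def test_p_on_the_permutation_grid(self, null_calls):
        pca = acoustics.run_pca(acoustics.temperature_adjust(null_calls))
        res = acoustics.permutation_test(pca, null_calls.groups, B=50, seed=2)
        for r in res.values():
            assert len(r.null_deltas) == 50
            assert round(r.p_value * 50, 9) == int(round(r.p_value * 50))
            assert 0 <= r.p_value <= 1
            assert r.p_value_downsampled is not None

    def test_seeded_determinism(self, null_calls):
        pca = acoustics.run_pca(acoustics.temperature_adjust(null_calls))
        r1 = acoustics.permutation_test(pca, null_calls.groups, B=30, seed=9)
        r2 = acoustics.permutation_test(pca, null_calls.groups, B=30, seed=9)
        for name in acoustics.STATISTIC_NAMES:
            np.testing.assert_array_equal(r1[name].null_deltas, r2[name].null_deltas)
            assert r1[name].p_value == r2[name].p_value

    def test_species_relabel_invariance(self, null_calls):
        # swapping species names A <-> B leaves overlap/centroid P unchanged
        pca = acoustics.run_pca(acoustics.temperature_adjust(null_calls))
        labels = np.array(null_calls.groups)
        swap = {
            genio.GROUP_ALLO_A: genio.GROUP_ALLO_B,
            genio.GROUP_ALLO_B: genio.GROUP_ALLO_A,
            genio.GROUP_PARA_A: genio.GROUP_PARA_B,
            genio.GROUP_PARA_B: genio.GROUP_PARA_A,
        }
        swapped = np.array([swap[g] for g in labels])
        r1 = acoustics.permutation_test(pca, labels, B=40, seed=3, downsample_to=None)
        r2 = acoustics.permutation_test(pca, swapped, B=40, seed=3, downsample_to=None)
        for name in ("overlap", "centroid_distance"):
            assert r1[name].p_value == r2[name].p_value

    def test_downsampling_reduces_group_sizes(self, null_calls):
        labels = np.array(null_calls.groups)
        rng = np.random.default_rng(0)
        keep = acoustics._downsample_mask(labels, 10, rng)
        sizes = {g: int(np.sum(labels[keep] == g)) for g in genio.CALL_GROUPS}
        assert sizes == {
            genio.GROUP_ALLO_A: 10, genio.GROUP_ALLO_B: 10,
            genio.GROUP_PARA_A: 9, genio.GROUP_PARA_B: 10,
        }

    def test_downsample_below_three_is_an_error(self, null_calls):
        pca = acoustics.run_pca(acoustics.temperature_adjust(null_calls))
        with pytest.raises(ValueError, match="below 3"):
            acoustics.permutation_test(pca, null_calls.groups, B=5, seed=0, downsample_to=2)

    def test_b_zero_is_an_error(self, null_calls):
        pca = acoustics.run_pca(acoustics.temperature_adjust(null_calls))
        with pytest.raises(ValueError, match="permutation"):
            acoustics.permutation_test(pca, null_calls.groups, B=0)


class TestReportTables:
    def test_results_table_shape(self, null_calls):
        pca = acoustics.run_pca(acoustics.temperature_adjust(null_calls))
        res = acoustics.permutation_test(pca, null_calls.groups, B=20, seed=1)
        df = acoustics.results_table(res)
        assert list(df["statistic"]) == list(acoustics.STATISTIC_NAMES)
        assert {"allopatric", "parapatric", "delta", "p_value", "p_value_downsampled"} <= set(df.columns)
        nulls = acoustics.null_samples_table(res)
        assert nulls.shape == (20, 5)
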