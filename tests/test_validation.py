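"""Validation statistics: comparison statistic, GOF tests, breakpoint fit."""

import numpy as np
import pytest

import corridorcast as cc
from corridorcast.validation import (
    ComparisonResult,
    SegmentedRegression,
    chisq_gof,
    mann_whitney,
    paired_t,
    rank_use,
    truncate_2dp,
)


class TestConvexPolygon:
    def test_square_with_interior_points(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5], [0.2, 0.8]])
        hull = cc.convex_polygon(pts)
        assert hull.area == pytest.approx(1.0)

    def test_hull_of_hull_is_hull(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 10, (50, 2))
        h1 = cc.convex_polygon(pts)
        h2 = cc.convex_polygon(np.asarray(h1.exterior.coords))
        assert h1.equals_exact(h2, 1e-9)

    def test_hull_contains_all_points_halfplane_check(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 10, (50, 2))
        hull = cc.convex_polygon(pts)
        verts = np.asarray(hull.exterior.coords)[:-1]
        # every point lies on the inner side of every hull edge
        for a, b in zip(verts, np.roll(verts, -1, axis=0)):
            ex, ey = b - a
            cross = ex * (pts[:, 1] - a[1]) - ey * (pts[:, 0] - a[0])
            assert (cross >= -1e-9).all() or (cross <= 1e-9).all()

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            cc.convex_polygon(np.array([[0, 0], [1, 1], [2, 2], [3, 3]]))


class TestComparisonStatistic:
    @pytest.mark.parametrize(
        "area,points,expect",
        [(97.0, 96.0, 1.01), (42.0, 81.0, 0.51), (49.0, 95.0, 0.51)],
    )
    def test_reported_percentage_pairs(self, area, points, expect):
        res = ComparisonResult("model", area, points)
        assert res.statistic == pytest.approx(area / points)
        assert res.statistic_2dp == expect

    def test_saturated_mask_gives_unity(self, e2e_run):
        stats = e2e_run["stats"]["LCN"]
        assert stats.area_pct <= 100 and stats.points_pct <= 100

    def test_full_mask_statistic_exactly_one(self):
        class FullMask:
            mask = np.ones((20, 20), dtype=bool)
            cell_size = 2.0
            origin = (0.0, 40.0)

        pts = np.array([[5.0, 5.0], [30.0, 30.0], [10.0, 35.0]])
        hull = cc.convex_polygon(pts)
        res = cc.comparison_statistic(FullMask(), hull, pts)
        assert res.area_pct == 100.0 and res.points_pct == 100.0
        assert res.statistic == 1.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        mask = rng.random((30, 30)) < 0.4

        def make(origin):
            class M:
                pass

            M.mask = mask
            M.cell_size = 2.0
            M.origin = origin
            return M()

        pts = rng.uniform(5, 55, (25, 2))
        hull = cc.convex_polygon(pts)
        base = cc.comparison_statistic(make((0.0, 60.0)), hull, pts)
        shift = np.array([37.0, -12.0])
        from shapely import affinity

        hull2 = affinity.translate(hull, *shift)
        moved = cc.comparison_statistic(
            make((0.0 + shift[0], 60.0 + shift[1])), hull2, pts + shift
        )
        assert moved.area_pct == pytest.approx(base.area_pct)
        assert moved.points_pct == pytest.approx(base.points_pct)

    def test_enlarging_mask_never_decreases_either_pct(self):
        rng = np.random.default_rng(3)
        small_mask = rng.random((30, 30)) < 0.3
        big_mask = small_mask | (rng.random((30, 30)) < 0.3)

        def make(mask):
            class M:
                pass

            M.mask = mask
            M.cell_size = 2.0
            M.origin = (0.0, 60.0)
            return M()

        pts = rng.uniform(5, 55, (40, 2))
        hull = cc.convex_polygon(pts)
        small = cc.comparison_statistic(make(small_mask), hull, pts)
        big = cc.comparison_statistic(make(big_mask), hull, pts)
        assert big.area_pct >= small.area_pct
        assert big.points_pct >= small.points_pct

    def test_truncation_convention(self):
        assert truncate_2dp(0.5185) == 0.51
        assert truncate_2dp(1.0104) == 1.01


class TestChiSquare:
    def test_exact_fit_gives_zero(self):
        res = chisq_gof({"a": 30, "b": 70}, {"a": 0.3, "b": 0.7})
        assert res.chi2 == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_textbook_two_cell_value(self):
        res = chisq_gof({"a": 10, "b": 0}, {"a": 0.5, "b": 0.5})
        assert res.chi2 == pytest.approx(10.0)
        assert res.df == 1

    def test_subdivided_components_nonnegative_and_independent(self):
        res = chisq_gof(
            {"a": 50, "b": 30, "c": 20}, {"a": 0.5, "b": 0.25, "c": 0.25}
        )
        assert (res.subdivided["chi2"] >= 0).all()
        assert (res.subdivided["df"] == 1).all()
        assert res.df == 2

    def test_type_one_error_calibration_under_null(self):
        rng = np.random.default_rng(7)
        weights = {"a": 0.4, "b": 0.35, "c": 0.25}
        p = np.array(list(weights.values()))
        rejections = 0
        reps = 2000
        for _ in range(reps):
            counts = rng.multinomial(120, p)
            res = chisq_gof(dict(zip(weights, counts)), weights)
            rejections += res.pvalue < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


class TestPairedT:
    def test_recorded_movement_table_value(self, table3):
        t, df, p = paired_t(table3["euclidean_km"], table3["path_km"])
        assert t == pytest.approx(-5.104, abs=5e-4)
        assert df == 9
        assert p < 0.001

    def test_zero_variance_differences_error(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_sign_convention_shift(self):
        rng = np.random.default_rng(8)
        b = rng.normal(0, 1, 500)
        a = b + 1 + rng.normal(0, 0.2, 500)
        t, df, p = paired_t(b, a)  # a larger => negative t
        assert t < -20


class TestMannWhitney:
    def test_identical_samples_half_n_squared(self):
        x = np.arange(20.0)
        u, p = mann_whitney(x, x)
        assert u == pytest.approx(20 * 20 / 2)

    def test_complete_separation_extreme(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert u == 0.0

    def test_u_matches_bruteforce_pair_count(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.5, 1, 30)
        u, _ = mann_whitney(x, y)
        brute = sum(
            1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in x for yj in y
        )
        assert u == pytest.approx(brute)


class TestRandomMatrixPoints:
    def test_deterministic_under_seed(self, demo_landscape):
        lc, rt = demo_landscape.landcover, demo_landscape.resistance_table
        a = cc.random_matrix_points(lc, rt, 50, seed=5)
        b = cc.random_matrix_points(lc, rt, 50, seed=5)
        np.testing.assert_array_equal(a, b)
        assert len(cc.random_matrix_points(lc, rt, 0, seed=5)) == 0

    def test_points_fall_only_in_matrix(self, demo_landscape):
        land = demo_landscape
        pts = cc.random_matrix_points(land.landcover, land.resistance_table, 300, seed=1)
        for x, y in pts:
            r, c = land.patches.world_to_cell(x, y)
            assert land.patches.labels[r, c] == 0

    def test_uniform_occupancy_over_halved_raster(self):
        grid = np.ones((20, 20), dtype=int)
        grid[:, 10:] = 3
        lc = cc.LandCoverRaster(grid, 2.0, (0.0, 40.0), {1: "Grass", 3: "Broadleaf"})
        rt = cc.table1_fixture()
        pts = cc.random_matrix_points(lc, rt, 10000, seed=2)
        assert (pts[:, 0] < 20.0).all()  # matrix is the west half
        counts, _ = np.histogram(pts[:, 1], bins=8, range=(0, 40))
        res = chisq_gof(
            {i: c for i, c in enumerate(counts)}, {i: 1.0 for i in range(8)}
        )
        assert res.pvalue > 0.01


class TestBreakpointRegression:
    def test_noiseless_two_segments_recovered_exactly(self):
        x = np.linspace(0, 100, 101)  # the join at 25 is an observed x
        y = np.where(x <= 25, 2.0 * x + 1.0, 2.0 * 25 + 1.0 - 0.5 * (x - 25))
        res = cc.breakpoint_regression(x, y)
        assert res.breakpoint_m == pytest.approx(25.0)
        assert res.left_slope == pytest.approx(2.0, abs=1e-8)
        assert res.right_slope == pytest.approx(-0.5, abs=1e-8)
        assert res.rss == pytest.approx(0.0, abs=1e-12)

    def test_hinge_recovery_under_noise(self):
        hits = 0
        for seed in range(20):
            x, y = cc.hinge_observations(n=500, noise_sd=5.0, seed=seed)
            res = cc.breakpoint_regression(x, y)
            hits += abs(res.breakpoint_m - 40.0) <= 5.0
        assert hits >= 18  # >= 90% of seeds

    def test_linear_data_break_unsupported(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 100, 200)
        y = 3.0 + 0.5 * x + rng.normal(0, 1.0, 200)
        res = cc.breakpoint_regression(x, y)
        assert not res.supported
        assert res.rss <= res.rss_linear + 1e-9

    def test_rss_never_worse_than_single_line(self):
        rng = np.random.default_rng(11)
        for seed in range(5):
            x, y = cc.hinge_observations(n=100, noise_sd=8.0, seed=seed)
            res = cc.breakpoint_regression(x, y)
            assert res.rss <= res.rss_linear + 1e-9

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            SegmentedRegression(np.full(20, 7.0), np.arange(20.0))

    def test_summary_mentions_breakpoint(self):
        x, y = cc.hinge_observations(n=100, seed=0)
        text = cc.breakpoint_regression(x, y).summary()
        assert "breakpoint" in text


class TestRankUse:
    def test_equal_use_alphabetical(self):
        frame = rank_use({"b": 10, "a": 10}, {"b": 10, "a": 10})
        assert list(frame.index) == ["a", "b"]

    def test_overused_group_first(self):
        frame = rank_use({"a": 10, "b": 20, "c": 10}, {"a": 10, "b": 10, "c": 10})
        assert frame.index[0] == "b"

    def test_constructed_feature_order(self):
        observed = {"river corridor": 60, "road/road verge": 40, "track/path": 30,
                    "field edge": 12, "habitat edge": 5}
        expected = {"river corridor": 20, "road/road verge": 20, "track/path": 20,
                    "field edge": 20, "habitat edge": 20}
        frame = rank_use(observed, expected)
        assert list(frame.index) == ["river corridor", "road/road verge",
                                     "track/path", "field edge", "habitat edge"]

    def test_zero_expectation_ranks_first(self):
        frame = rank_use({"a": 5, "b": 50}, {"a": 0, "b": 50})
        assert frame.index[0] == "a"
        assert np.isinf(frame["ratio"].iloc[0])
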