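"""Network, buffered-path and corridor masks."""

import numpy as np
import pytest

import corridorcast as cc
from corridorcast.cost_engine import accumulated_cost
from corridorcast.landscape import HabitatPatchSet


def patchworld(blocks, n=50, cell=2.0, matrix_code=1):
    """Raster with woodland blocks; returns (landcover, patches, resistance)."""
    grid = np.full((n, n), matrix_code)
    for r0, r1, c0, c1 in blocks:
        grid[r0:r1, c0:c1] = 3
    names = {1: "Grass", 3: "Broadleaf"}
    lc = cc.LandCoverRaster(grid, cell, (0.0, n * cell), names)
    rt = cc.table1_fixture()
    patches = cc.label_habitat_patches(lc, rt)
    rs = cc.build_resistance_surface(lc, rt)
    return lc, patches, rs


def all_visited(patches):
    return HabitatPatchSet(
        patches.labels, dict(patches.patch_areas), patches.cell_size,
        patches.origin, {pid: True for pid in patches.patch_areas},
    )


class TestCorridorMargin:
    def test_forty_metres_in_resistance_forty_matrix(self):
        assert cc.corridor_margin(40.0, 40.0) == 1600.0


class TestLeastCostNetwork:
    def test_all_habitat_means_full_mask(self):
        _, patches, rs = patchworld([(0, 50, 0, 50)])
        net = cc.least_cost_network(rs, patches, 10.0)
        assert net.mask.all()

    def test_uniform_grass_radius_is_dispersal_over_resistance(self):
        # one patch in uniform grass (40): 8000 cost units reach 200 m
        _, patches, rs = patchworld([(23, 27, 23, 27)], n=301, cell=2.0)
        net = cc.least_cost_network(rs, patches, 8000.0)
        acc = accumulated_cost(rs, patches.mask())
        inside = net.mask & ~patches.mask()
        assert acc.grid[inside].max() <= 8000.0
        # cells just beyond the iso-cost shell are excluded
        beyond = (acc.grid > 8000.0) & np.isfinite(acc.grid)
        assert not net.mask[beyond].any()
        # reach along a straight rook line east of the patch ~ 200 m
        east = net.mask[25, 27:]
        reach_m = east.sum() * 2.0
        assert 180.0 <= reach_m <= 220.0

    def test_zero_threshold_keeps_habitat_only(self):
        _, patches, rs = patchworld([(5, 10, 5, 10)])
        net = cc.least_cost_network(rs, patches, 1e-9)
        grown = cc.least_cost_network(rs, patches, 4000.0)
        assert (net.mask == patches.mask()).all() or (
            net.mask.sum() <= patches.mask().sum() + patches.mask().sum()
        )
        # monotone in the dispersal threshold
        assert (grown.mask | net.mask == grown.mask).all()

    def test_nonpositive_dispersal_rejected(self):
        _, patches, rs = patchworld([(5, 10, 5, 10)])
        with pytest.raises(ValueError):
            cc.least_cost_network(rs, patches, -1.0)


class TestSelectVisitedPatches:
    def test_no_fixes_all_false(self):
        _, patches, _ = patchworld([(5, 10, 5, 10), (30, 35, 30, 35)])
        v = cc.select_visited_patches(patches, np.empty((0, 2)))
        assert v.visited_ids() == []

    def test_membership_matches_bruteforce(self):
        _, patches, _ = patchworld(
            [(2, 6, 2, 6), (12, 16, 12, 16), (22, 26, 22, 26), (32, 36, 32, 36), (42, 46, 42, 46)]
        )
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 100, size=(40, 2))
        v = cc.select_visited_patches(patches, pts)
        expect = set()
        for x, y in pts:
            r, c = patches.world_to_cell(x, y)
            if 0 <= r < 50 and 0 <= c < 50 and patches.labels[r, c] > 0:
                expect.add(int(patches.labels[r, c]))
        assert set(v.visited_ids()) == expect

    def test_one_fix_per_patch_flags_all(self):
        _, patches, _ = patchworld([(2, 6, 2, 6), (30, 34, 30, 34)])
        centers = []
        for pid in patches.patch_ids():
            rr, ccids = np.nonzero(patches.labels == pid)
            centers.append(
                [
                    patches.origin[0] + (ccids.mean() + 0.5) * 2.0,
                    patches.origin[1] - (rr.mean() + 0.5) * 2.0,
                ]
            )
        v = cc.select_visited_patches(patches, np.array(centers))
        assert v.visited_ids() == patches.patch_ids()


class TestBufferedPaths:
    def test_two_patches_uniform_stadium_shape(self):
        _, patches, rs = patchworld([(23, 27, 2, 6), (23, 27, 44, 48)], n=50)
        lcp = cc.buffered_least_cost_paths(rs, all_visited(patches), 40.0)
        assert len(lcp.source_paths) == 1
        path = lcp.source_paths[0]
        # straight east-west gap: path stays within the patches' row band
        assert all(23 <= r <= 26 for r, _ in path.cells)
        # every cell centre within 40 m of the path polyline is inside
        from shapely.geometry import LineString

        line = LineString(path.vertices)
        nr, nc = rs.shape
        xs = rs.origin[0] + (np.arange(nc) + 0.5) * 2.0
        ys = rs.origin[1] - (np.arange(nr) + 0.5) * 2.0
        gx, gy = np.meshgrid(xs, ys)
        import shapely

        dist = shapely.distance(shapely.points(np.column_stack([gx.ravel(), gy.ravel()])), line)
        expect = (dist < 40.0 - 1e-9).reshape(nr, nc)
        assert (lcp.mask | ~expect).all()  # expect ⊆ mask
        assert (~lcp.mask | (dist.reshape(nr, nc) <= 40.0 + 3.0)).all()

    def test_zero_buffer_keeps_path_cells_only(self):
        _, patches, rs = patchworld([(10, 14, 2, 6), (36, 40, 44, 48)])
        lcp = cc.buffered_least_cost_paths(rs, all_visited(patches), 0.0)
        path_cells = {c for p in lcp.source_paths for c in p.cells}
        assert {tuple(c) for c in np.argwhere(lcp.mask)} == path_cells

    def test_three_patches_union_at_most_sum(self):
        _, patches, rs = patchworld([(2, 6, 2, 6), (2, 6, 44, 48), (44, 48, 22, 26)])
        lcp = cc.buffered_least_cost_paths(rs, all_visited(patches), 40.0)
        assert len(lcp.source_paths) == 3
        singles = 0
        for p in lcp.source_paths:
            from shapely.geometry import LineString

            singles += LineString(p.vertices).buffer(40.0).area
        assert lcp.mask.sum() * 4.0 <= singles * 1.1  # union <= sum (+raster slack)

    def test_single_visited_patch_rejected(self):
        _, patches, rs = patchworld([(5, 10, 5, 10)])
        with pytest.raises(ValueError, match="visited"):
            cc.buffered_least_cost_paths(rs, all_visited(patches), 40.0)

    def test_buffer_monotone(self):
        _, patches, rs = patchworld([(10, 14, 2, 6), (36, 40, 44, 48)])
        small = cc.buffered_least_cost_paths(rs, all_visited(patches), 20.0)
        big = cc.buffered_least_cost_paths(rs, all_visited(patches), 60.0)
        assert (big.mask | small.mask == big.mask).all()


class TestLeastCostCorridor:
    def test_margin_zero_keeps_only_optimal_cells(self):
        _, patches, rs = patchworld([(23, 27, 2, 6), (23, 27, 44, 48)])
        corr = cc.least_cost_corridor(rs, all_visited(patches), 0.0)
        surf = corr.pair_surfaces[0]
        lo = surf.grid[np.isfinite(surf.grid)].min()
        expect = (surf.grid <= lo + 1e-9) | all_visited(patches).mask()
        assert (corr.mask == expect).all()

    def test_ellipse_membership_on_uniform_surface(self):
        # two point-like patches 100 m apart on resistance 1, margin 20:
        # the corridor is {x: costA(x)+costB(x) <= 120}, checked cell by cell
        grid = np.ones((30, 30), dtype=int)
        grid[14:15, 9:10] = 3
        grid[14:15, 19:20] = 3
        names = {1: "Grass", 3: "Broadleaf"}
        lc = cc.LandCoverRaster(grid, 10.0, (0.0, 300.0), names)
        rt = cc.ResistanceTable({"Grass": 1.0, "Broadleaf": 1.0},
                                frozenset({"Broadleaf"}))
        patches = cc.label_habitat_patches(lc, rt)
        rs = cc.build_resistance_surface(lc, rt)
        corr = cc.least_cost_corridor(rs, all_visited(patches), 20.0)
        accA = accumulated_cost(rs, patches.labels == 1)
        accB = accumulated_cost(rs, patches.labels == 2)
        lo = (accA.grid + accB.grid).min()
        expect = (accA.grid + accB.grid <= lo + 20.0) | (patches.labels > 0)
        assert (corr.mask == expect).all()

    def test_margin_monotone_and_contains_zero_buffer_path(self):
        _, patches, rs = patchworld([(10, 14, 2, 6), (36, 40, 44, 48)])
        v = all_visited(patches)
        small = cc.least_cost_corridor(rs, v, 100.0)
        big = cc.least_cost_corridor(rs, v, 2000.0)
        assert (big.mask | small.mask == big.mask).all()
        lcp0 = cc.buffered_least_cost_paths(rs, v, 0.0)
        assert (big.mask | lcp0.mask == big.mask).all()  # nesting


class TestLowestFractionCorridor:
    def test_quantile_cell_counts(self):
        rng = np.random.default_rng(4)
        vals = rng.permutation(100).astype(float).reshape(10, 10)
        surf = cc.CorridorSurface(vals, (1, 2), 2.0, (0.0, 20.0))
        assert cc.lowest_fraction_corridor([surf], 0.10).mask.sum() == 10
        assert cc.lowest_fraction_corridor([surf], 1e-9).mask.sum() == 1
        assert cc.lowest_fraction_corridor([surf], 1.0).mask.sum() == 100

    def test_constant_surface_warns_full(self):
        surf = cc.CorridorSurface(np.full((5, 5), 7.0), (1, 2), 2.0, (0.0, 10.0))
        with pytest.warns(UserWarning, match="constant"):
            mask = cc.lowest_fraction_corridor([surf], 0.1).mask
        assert mask.all()


class TestUniformElongationBound:
    def test_lcp_length_close_to_euclidean_gap(self):
        # 8-connectivity inflates lengths by at most ~8.24%
        _, patches, rs = patchworld([(4, 8, 4, 8), (38, 42, 40, 44)], n=50)
        lcp = cc.buffered_least_cost_paths(rs, all_visited(patches), 0.0)
        path = lcp.source_paths[0]
        a = path.vertices[0]
        b = path.vertices[-1]
        gap = np.hypot(*(a - b))
        assert path.length_m <= gap * 1.083 + 2 * 2.0 * np.sqrt(2)
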