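"""Shared fixtures: tiny rasters, the reference tables, a brute-force
shortest-path oracle, and one session-scoped synthetic end-to-end run."""

from __future__ import annotations

import numpy as np
import pytest

import corridorcast as cc
from corridorcast.movement import identify_clusters, point_density, segment_movements


def bellman_ford_costs(resistance: np.ndarray, cell_size: float,
                       sources: list[tuple[int, int]]) -> np.ndarray:
    """Independent exhaustive shortest-path oracle on the 8-neighbour grid.

    Plain relaxation until a fixed point: no priority queue, no shared code
    with the implementation under test.
    """
    nr, nc = resistance.shape
    dist = np.full((nr, nc), np.inf)
    for s in sources:
        dist[s] = 0.0
    moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    changed = True
    while changed:
        changed = False
        for r in range(nr):
            for c in range(nc):
                if not np.isfinite(dist[r, c]):
                    continue
                for dr, dc in moves:
                    b = (r + dr, c + dc)
                    if not (0 <= b[0] < nr and 0 <= b[1] < nc):
                        continue
                    d = cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
                    step = (resistance[r, c] + resistance[b]) / 2.0 * d
                    if dist[r, c] + step < dist[b] - 1e-12:
                        dist[b] = dist[r, c] + step
                        changed = True
    return dist


TABLE1_VALUES = np.array([1, 16, 40, 37, 27, 91, 130, 72, 55, 1000], dtype=float)


@pytest.fixture(scope="session")
def table1():
    return cc.table1_fixture()


@pytest.fixture(scope="session")
def table3():
    return cc.table3_fixture()


@pytest.fixture()
def uniform_surface():
    """10x10 uniform resistance-1 surface with 10 m cells."""
    return cc.ResistanceSurface(np.ones((10, 10)), 10.0, (0.0, 100.0))


@pytest.fixture(scope="session")
def demo_landscape():
    return cc.generate_landscape(cc.LandscapeSpec(seed=0))


@pytest.fixture(scope="session")
def e2e_run(demo_landscape):
    """One full synthetic study: five feature-biased collared animals on the
    demo landscape, segmented into movements, with all three connectivity
    models and their comparison statistics."""
    land = demo_landscape
    rs = cc.build_resistance_surface(land.landcover, land.resistance_table)
    movements, point_blocks = [], []
    tracks = []
    for s in range(5):
        sim = cc.simulate_track(
            land, cc.WalkSpec.feature_biased(seed=s), duration_h=6.0,
            animal_id=f"sim{s}",
        )
        tracks.append(sim)
        track = sim.observed
        dens = point_density(track, 30.0)
        clusters = identify_clusters(track, dens, 5, land.patches)
        for m in segment_movements(track, clusters):
            movements.append(m)
            i0, i1 = m.fix_indices
            point_blocks.append(track.xy[i0 : i1 + 1])
    points = np.vstack(point_blocks)
    visited = cc.select_visited_patches(land.patches, points)
    network = cc.least_cost_network(rs, land.patches, 8000.0)
    lcp = cc.buffered_least_cost_paths(rs, visited, 40.0)
    lcc = cc.least_cost_corridor(rs, visited, 1600.0)
    hull = cc.convex_polygon(points)
    stats = {
        name: cc.comparison_statistic(mobj, hull, points, name)
        for name, mobj in (("LCN", network), ("LCP", lcp), ("LCC", lcc))
    }
    return {
        "land": land,
        "rs": rs,
        "tracks": tracks,
        "movements": movements,
        "points": points,
        "visited": visited,
        "network": network,
        "lcp": lcp,
        "lcc": lcc,
        "hull": hull,
        "stats": stats,
    }
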