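"""The three least-cost landscape models as binary masks.

* **Least-cost network (LCN)** — habitat plus every matrix cell whose
  accumulated cost from the habitat set stays under a threshold derived
  from a maximum dispersal distance (default 8 km => 8000 cost units,
  since one cost unit is one metre at habitat resistance 1).  The broad
  "everywhere the animal could move" model.
* **Buffered least-cost paths (LCP)** — the pairwise minimum-cost routes
  between visited habitat patches, buffered by a fixed Euclidean distance
  (default 40 m each side).
* **Least-cost corridor (LCC)** — per patch pair, all cells whose
  two-sided cost sum is within a margin (default 1600 cost units, the
  cost of moving 40 m through resistance-40 matrix) of the optimal path
  cost: a swath of near-optimal routes of varying width.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import shapely
from shapely.geometry import LineString, Point

from .cost_engine import (
    AccumulatedCostSurface,
    CorridorSurface,
    LeastCostPath,
    accumulated_cost,
    corridor_surface,
    path_between_masks,
)
from .landscape import HabitatPatchSet, ResistanceSurface

__all__ = [
    "NetworkMask",
    "BufferedPathMask",
    "CorridorMask",
    "corridor_margin",
    "least_cost_network",
    "select_visited_patches",
    "buffered_least_cost_paths",
    "least_cost_corridor",
    "lowest_fraction_corridor",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_DISPERSAL_M = 8000.0
DEFAULT_BUFFER_M = 40.0
DEFAULT_CORRIDOR_MARGIN = 1600.0


def corridor_margin(buffer_m: float, matrix_resistance: float) -> float:
    """Cost-unit margin equivalent to moving ``buffer_m`` metres through the
    dominant matrix land cover (40 m at resistance 40 -> 1600 cost units)."""
    return buffer_m * matrix_resistance


@dataclass
class NetworkMask:
    mask: np.ndarray
    max_dispersal_m: float
    cost_threshold: float
    cell_size: float
    origin: tuple[float, float]


@dataclass
class BufferedPathMask:
    mask: np.ndarray
    buffer_m: float
    source_paths: list[LeastCostPath]
    cell_size: float
    origin: tuple[float, float]
    skipped_pairs: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class CorridorMask:
    mask: np.ndarray
    corridor_margin: float
    pair_surfaces: list[CorridorSurface]
    cell_size: float
    origin: tuple[float, float]
    skipped_pairs: list[tuple[int, int]] = field(default_factory=list)


def least_cost_network(
    rs: ResistanceSurface,
    patches: HabitatPatchSet,
    max_dispersal_m: float = DEFAULT_MAX_DISPERSAL_M,
    habitat_resistance: float = 1.0,
    barrier_threshold: float | None = None,
) -> NetworkMask:
    """Habitat network: habitat cells plus matrix reachable within budget.

    The cost threshold is ``max_dispersal_m x habitat_resistance`` — for
    the default 8 km dispersal at resistance 1, 8000 cost units.
    """
    if max_dispersal_m <= 0:
        raise ValueError("max dispersal distance must be positive")
    if patches.n_patches < 1:
        raise ValueError("at least one habitat patch is required")
    threshold = max_dispersal_m * habitat_resistance
    habitat = patches.mask()
    acc = accumulated_cost(rs, habitat, barrier_threshold)
    mask = habitat | (acc.grid <= threshold)
    return NetworkMask(mask, max_dispersal_m, threshold, rs.cell_size, rs.origin)


def select_visited_patches(patches: HabitatPatchSet, fixes) -> HabitatPatchSet:
    """Flag patches that contain at least one GPS fix.

    ``fixes`` is an (n, 2) array of world (x, y) coordinates, or an
    iterable of objects with ``.xy`` arrays (GPSTrack instances).
    """
    pts = _collect_points(fixes)
    flags = {pid: False for pid in patches.patch_areas}
    nr, nc = patches.labels.shape
    for x, y in pts:
        r, c = patches.world_to_cell(x, y)
        if 0 <= r < nr and 0 <= c < nc:
            pid = int(patches.labels[r, c])
            if pid > 0:
                flags[pid] = True
    return HabitatPatchSet(
        patches.labels, dict(patches.patch_areas), patches.cell_size,
        patches.origin, flags,
    )


def _collect_points(fixes) -> np.ndarray:
    if hasattr(fixes, "xy"):
        return np.asarray(fixes.xy, dtype=float)
    arr = np.asarray(fixes, dtype=object)
    if arr.dtype != object:
        return np.asarray(fixes, dtype=float).reshape(-1, 2)
    pts = []
    for item in fixes:
        pts.append(np.asarray(item.xy if hasattr(item, "xy") else item, float).reshape(-1, 2))
    if not pts:
        return np.empty((0, 2))
    return np.vstack(pts)


def _pairwise_paths(
    rs: ResistanceSurface,
    visited: HabitatPatchSet,
    barrier_threshold: float | None,
):
    """Yield (pair, path-or-None) for every unordered visited-patch pair."""
    ids = visited.visited_ids()
    if len(ids) < 2:
        raise ValueError(
            f"need >= 2 visited patches for pairwise models, got {len(ids)}"
        )
    for a, b in combinations(ids, 2):
        path = path_between_masks(
            rs, visited.mask(a), visited.mask(b), barrier_threshold
        )
        yield (a, b), path


def buffered_least_cost_paths(
    rs: ResistanceSurface,
    visited: HabitatPatchSet,
    buffer_m: float = DEFAULT_BUFFER_M,
    barrier_threshold: float | None = None,
) -> BufferedPathMask:
    """Union of Euclidean buffers around all pairwise least-cost paths.

    Each visited patch pair contributes the minimum-cost traverse between
    the two patches (whole patches act as source/target, so paths connect
    patch boundaries).  Buffering happens in vector space on the path
    polyline, then the buffer polygon is rasterized by cell-centre test.
    Unreachable pairs are skipped with a warning and recorded.
    """
    if buffer_m < 0:
        raise ValueError("buffer distance must be >= 0")
    mask = np.zeros(rs.grid.shape, dtype=bool)
    paths: list[LeastCostPath] = []
    skipped: list[tuple[int, int]] = []
    geoms = []
    for pair, path in _pairwise_paths(rs, visited, barrier_threshold):
        if path is None:
            warnings.warn(f"patch pair {pair} is unreachable; skipped", stacklevel=2)
            skipped.append(pair)
            continue
        paths.append(path)
        for r, c in path.cells:
            mask[r, c] = True
        if buffer_m > 0 and len(path.vertices) >= 1:
            line = (
                LineString(path.vertices)
                if len(path.vertices) >= 2
                else Point(path.vertices[0])
            )
            geoms.append(line.buffer(buffer_m))
    if geoms:
        mask |= _rasterize_polygons(geoms, rs)
    return BufferedPathMask(mask, buffer_m, paths, rs.cell_size, rs.origin, skipped)


def _rasterize_polygons(geoms, rs: ResistanceSurface) -> np.ndarray:
    union = shapely.union_all(geoms)
    nr, nc = rs.grid.shape
    xs = rs.origin[0] + (np.arange(nc) + 0.5) * rs.cell_size
    ys = rs.origin[1] - (np.arange(nr) + 0.5) * rs.cell_size
    gx, gy = np.meshgrid(xs, ys)
    return shapely.contains_xy(union, gx.ravel(), gy.ravel()).reshape(nr, nc)


def least_cost_corridor(
    rs: ResistanceSurface,
    visited: HabitatPatchSet,
    margin: float = DEFAULT_CORRIDOR_MARGIN,
    barrier_threshold: float | None = None,
) -> CorridorMask:
    """Union of per-pair corridor slices plus the visited habitat itself.

    For each visited patch pair the corridor slice is
    ``{x : costA(x) + costB(x) <= min_pair_cost + margin}`` — the
    near-optimal swath.  Thresholding is pairwise (each pair against its
    own optimum), then unioned.
    """
    if margin < 0:
        raise ValueError("corridor margin must be >= 0")
    ids = visited.visited_ids()
    if len(ids) < 2:
        raise ValueError(f"need >= 2 visited patches, got {len(ids)}")
    mask = np.zeros(rs.grid.shape, dtype=bool)
    surfaces: list[CorridorSurface] = []
    skipped: list[tuple[int, int]] = []
    acc_cache: dict[int, AccumulatedCostSurface] = {
        pid: accumulated_cost(rs, visited.mask(pid), barrier_threshold) for pid in ids
    }
    for a, b in combinations(ids, 2):
        surf = corridor_surface(acc_cache[a], acc_cache[b], pair=(a, b))
        finite = np.isfinite(surf.grid)
        if not finite.any():
            warnings.warn(f"patch pair {(a, b)} is unreachable; skipped", stacklevel=2)
            skipped.append((a, b))
            continue
        lo = surf.grid[finite].min()
        mask |= finite & (surf.grid <= lo + margin)
        surfaces.append(surf)
    for pid in ids:
        mask |= visited.mask(pid)
    return CorridorMask(mask, margin, surfaces, rs.cell_size, rs.origin, skipped)


def lowest_fraction_corridor(
    pair_surfaces: list[CorridorSurface], fraction: float
) -> CorridorMask:
    """Alternative corridor rule: keep the lowest ``fraction`` quantile of
    each pair surface (e.g. the lowest 10% of the cost surface)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if not pair_surfaces:
        raise ValueError("no corridor surfaces supplied")
    ref = pair_surfaces[0]
    mask = np.zeros(ref.grid.shape, dtype=bool)
    for surf in pair_surfaces:
        finite = np.isfinite(surf.grid)
        vals = surf.grid[finite]
        if vals.min() == vals.max():
            warnings.warn(
                "corridor surface is constant; returning the whole surface",
                stacklevel=2,
            )
            mask |= finite
            continue
        cutoff = np.quantile(vals, fraction)
        mask |= finite & (surf.grid <= cutoff)
    return CorridorMask(mask, np.nan, list(pair_surfaces), ref.cell_size, ref.origin)
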