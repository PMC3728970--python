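"""Accumulated-cost computation on resistance rasters.

Movement is modelled on the 8-connected grid graph.  The cost of one step
between adjacent cells a and b is::

    step_cost(a, b) = (r_a + r_b) / 2 * d(a, b)

with ``d`` = cell_size for rook moves and cell_size * sqrt(2) for diagonal
moves — the standard GIS cost-distance contract.  Costs therefore carry
units of resistance x metres ("cost units"; 1 cost unit = 1 m at
resistance 1).

The single-source / multi-source shortest-path solve goes through
:func:`scipy.sparse.csgraph.dijkstra`; the path backtrace is deterministic
with ties broken in the fixed neighbour order N, NE, E, SE, S, SW, W, NW.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .landscape import ResistanceSurface

__all__ = [
    "AccumulatedCostSurface",
    "LeastCostPath",
    "CorridorSurface",
    "accumulated_cost",
    "least_cost_path",
    "path_between_masks",
    "corridor_surface",
    "NEIGHBOR_OFFSETS",
]

# fixed backtrace tie-break order: N, NE, E, SE, S, SW, W, NW
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)


@dataclass
class AccumulatedCostSurface:
    """Least accumulated cost from a source set, per cell.

    ``grid`` holds the minimum over 8-connected paths of the summed step
    costs; exactly 0 on source cells, ``np.inf`` where unreachable.
    """

    grid: np.ndarray
    source_mask: np.ndarray
    cell_size: float
    origin: tuple[float, float]

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class LeastCostPath:
    """A single minimum-cost route between two cells (or cell sets)."""

    cells: list[tuple[int, int]]
    vertices: np.ndarray  # (n, 2) world coordinates of cell centres
    total_cost: float
    length_m: float


@dataclass
class CorridorSurface:
    """Two-sided cost sum: value(x) = accCost_from_A(x) + accCost_from_B(x).

    The minimum over the grid equals the least-cost-path cost between the
    two source sets; thresholding near the minimum yields a corridor.
    """

    grid: np.ndarray
    pair: tuple[int, int]
    cell_size: float
    origin: tuple[float, float]


def _step_lengths(cell_size: float) -> np.ndarray:
    return np.array(
        [cell_size * (np.sqrt(2.0) if dr and dc else 1.0) for dr, dc in NEIGHBOR_OFFSETS]
    )


def _grid_graph(rs: ResistanceSurface, barrier_threshold: float | None) -> coo_matrix:
    """Sparse 8-neighbour graph with mean-resistance step weights."""
    r = rs.grid
    nr, nc = r.shape
    n = nr * nc
    passable = np.ones_like(r, dtype=bool)
    if barrier_threshold is not None:
        passable = r < barrier_threshold
    rows_idx, cols_idx = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    src_all, dst_all, w_all = [], [], []
    lengths = _step_lengths(rs.cell_size)
    for (dr, dc), d in zip(NEIGHBOR_OFFSETS, lengths):
        r0 = slice(max(0, -dr), nr - max(0, dr))
        r1 = slice(max(0, dr), nr - max(0, -dr))
        c0 = slice(max(0, -dc), nc - max(0, dc))
        c1 = slice(max(0, dc), nc - max(0, -dc))
        ok = passable[r0, c0] & passable[r1, c1]
        a = (rows_idx[r0, c0] * nc + cols_idx[r0, c0])[ok]
        b = (rows_idx[r1, c1] * nc + cols_idx[r1, c1])[ok]
        w = ((r[r0, c0] + r[r1, c1]) / 2.0 * d)[ok]
        src_all.append(a)
        dst_all.append(b)
        w_all.append(w)
    return coo_matrix(
        (np.concatenate(w_all), (np.concatenate(src_all), np.concatenate(dst_all))),
        shape=(n, n),
    ).tocsr()


def accumulated_cost(
    rs: ResistanceSurface,
    sources: np.ndarray,
    barrier_threshold: float | None = None,
) -> AccumulatedCostSurface:
    """Least accumulated cost from a source cell set to every cell.

    Parameters
    ----------
    rs
        Resistance surface.
    sources
        Boolean grid, True on source cells (>= 1 required); cost is 0 there.
    barrier_threshold
        Cells with resistance >= this value are impassable (cost ``inf``).
        Default None: even extreme resistances (e.g. buildings at 1000)
        remain traversable at extreme cost.
    """
    sources = np.asarray(sources, dtype=bool)
    if sources.shape != rs.grid.shape:
        raise ValueError(
            f"source mask shape {sources.shape} != surface shape {rs.grid.shape}"
        )
    if not sources.any():
        raise ValueError("source mask is empty")
    graph = _grid_graph(rs, barrier_threshold)
    idx = np.flatnonzero(sources.ravel())
    dist = dijkstra(graph, directed=False, indices=idx, min_only=True)
    grid = dist.reshape(rs.grid.shape)
    if barrier_threshold is not None:
        grid[rs.grid >= barrier_threshold] = np.inf
    grid[sources] = 0.0
    return AccumulatedCostSurface(grid, sources, rs.cell_size, rs.origin)


def _cell_centers(cells: list[tuple[int, int]], cell_size: float, origin) -> np.ndarray:
    arr = np.asarray(cells, dtype=float)
    x = origin[0] + (arr[:, 1] + 0.5) * cell_size
    y = origin[1] - (arr[:, 0] + 0.5) * cell_size
    return np.column_stack([x, y])


def _backtrace(
    rs: ResistanceSurface,
    acc: AccumulatedCostSurface,
    end: tuple[int, int],
) -> LeastCostPath:
    """Walk downhill on the accumulated-cost grid from ``end`` to a source.

    At every step the neighbour minimising cost(b) + step_cost(b, cur) is
    taken; ties go to the first neighbour in the fixed N..NW order, which
    makes the path bit-reproducible.
    """
    nr, nc = acc.grid.shape
    lengths = _step_lengths(rs.cell_size)
    cells = [end]
    total_cost = 0.0
    length_m = 0.0
    cur = end
    D = acc.grid
    R = rs.grid
    while D[cur] > 0.0:
        best_val = np.inf
        best = None
        best_step = best_d = 0.0
        for (dr, dc), d in zip(NEIGHBOR_OFFSETS, lengths):
            b = (cur[0] + dr, cur[1] + dc)
            if not (0 <= b[0] < nr and 0 <= b[1] < nc):
                continue
            if not np.isfinite(D[b]):
                continue
            step = (R[cur] + R[b]) / 2.0 * d
            val = D[b] + step
            if val < best_val - 1e-12:
                best_val, best, best_step, best_d = val, b, step, d
        assert best is not None, "backtrace stalled: inconsistent cost surface"
        total_cost += best_step
        length_m += best_d
        cur = best
        cells.append(cur)
    cells.reverse()
    return LeastCostPath(
        cells=cells,
        vertices=_cell_centers(cells, rs.cell_size, rs.origin),
        total_cost=total_cost,
        length_m=length_m,
    )


def least_cost_path(
    rs: ResistanceSurface,
    start: tuple[int, int],
    end: tuple[int, int],
    barrier_threshold: float | None = None,
) -> LeastCostPath | None:
    """Minimum-cost path between two cells; ``None`` when end is unreachable."""
    if start == end:
        raise ValueError("start and end cells must differ")
    nr, nc = rs.grid.shape
    for cell in (start, end):
        if not (0 <= cell[0] < nr and 0 <= cell[1] < nc):
            raise ValueError(f"cell {cell} outside raster of shape {(nr, nc)}")
    sources = np.zeros(rs.grid.shape, dtype=bool)
    sources[start] = True
    acc = accumulated_cost(rs, sources, barrier_threshold)
    if not np.isfinite(acc.grid[end]):
        return None
    return _backtrace(rs, acc, end)


def path_between_masks(
    rs: ResistanceSurface,
    source_mask: np.ndarray,
    target_mask: np.ndarray,
    barrier_threshold: float | None = None,
) -> LeastCostPath | None:
    """Minimum-cost traverse between two cell sets (e.g. habitat patches).

    The whole source set is at cost 0, the endpoint is the cheapest cell of
    the target set, so the path connects the two set boundaries rather than
    any particular interior cell.  Returns ``None`` if the target is
    unreachable.
    """
    acc = accumulated_cost(rs, source_mask, barrier_threshold)
    masked = np.where(target_mask, acc.grid, np.inf)
    if not np.isfinite(masked.min()):
        return None
    end = np.unravel_index(int(masked.argmin()), masked.shape)
    if source_mask[end]:  # overlapping / adjacent sets: zero-cost degenerate path
        return LeastCostPath(
            cells=[end],
            vertices=_cell_centers([end], rs.cell_size, rs.origin),
            total_cost=0.0,
            length_m=0.0,
        )
    return _backtrace(rs, acc, end)


def corridor_surface(
    costA: AccumulatedCostSurface, costB: AccumulatedCostSurface, pair=(0, 0)
) -> CorridorSurface:
    """Element-wise sum of two accumulated-cost surfaces.

    The result is symmetric in A and B and its minimum equals the cost of
    the least-cost path between the two source sets.
    """
    if costA.grid.shape != costB.grid.shape:
        raise ValueError("accumulated-cost surfaces have different shapes")
    if costA.cell_size != costB.cell_size or costA.origin != costB.origin:
        raise ValueError("accumulated-cost surfaces are georeferenced differently")
    return CorridorSurface(
        costA.grid + costB.grid, tuple(pair), costA.cell_size, costA.origin
    )
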