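"""Categorical land-cover rasters, resistance surfaces and habitat patches.

The landscape world is a regular square grid in planar metric coordinates
(x east, y north).  Grid indices are (row, col) from the top-left cell and
the centre of cell (r, c) sits at::

    (origin_x + (c + 0.5) * cell_size,  origin_y - (r + 0.5) * cell_size)

where ``origin`` is the outer corner of the top-left cell.  All distances
are world metres.  A land-cover category maps to a dimensionless movement
resistance >= 1; cost accumulates as resistance x metres travelled, so one
cost unit equals one metre at resistance 1 (habitat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString

__all__ = [
    "LandCoverRaster",
    "ResistanceTable",
    "ResistanceSurface",
    "Feature",
    "FeatureSet",
    "HabitatPatchSet",
    "burn_linear_features",
    "build_resistance_surface",
    "label_habitat_patches",
]

#: default rasterization cell size (m); 4 m linear features stay >= 2 cells wide
DEFAULT_CELL_SIZE = 2.0

FEATURE_TYPES = (
    "field edge",
    "habitat edge",
    "path",
    "river/stream",
    "road",
    "road verge",
    "track",
)


@dataclass
class LandCoverRaster:
    """Categorical land-cover grid.

    Parameters
    ----------
    grid
        2-D integer array of category codes.
    cell_size
        Metres per cell edge (> 0).
    origin
        World (x, y) of the outer corner of the top-left cell.
    category_names
        Mapping code -> category label; every code present in ``grid``
        must have an entry.
    """

    grid: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    category_names: dict[int, str]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or min(self.grid.shape) < 2:
            raise ValueError("land-cover grid must be 2-D and at least 2x2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        present = set(np.unique(self.grid).tolist())
        missing = present - set(self.category_names)
        if missing:
            raise ValueError(f"codes without category names: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World (x, y) coordinate arrays of every cell centre."""
        nr, nc = self.grid.shape
        xs = self.origin[0] + (np.arange(nc) + 0.5) * self.cell_size
        ys = self.origin[1] - (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def world_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Grid (row, col) containing world point (x, y)."""
        c = int(np.floor((x - self.origin[0]) / self.cell_size))
        r = int(np.floor((self.origin[1] - y) / self.cell_size))
        return r, c

    def contains(self, x: float, y: float) -> bool:
        r, c = self.world_to_cell(x, y)
        nr, nc = self.grid.shape
        return 0 <= r < nr and 0 <= c < nc

    def copy(self) -> "LandCoverRaster":
        return LandCoverRaster(
            self.grid.copy(), self.cell_size, self.origin, dict(self.category_names)
        )


@dataclass
class ResistanceTable:
    """Category label -> movement resistance, with the habitat subset.

    Resistances are dimensionless rates >= 1; habitat categories carry
    resistance exactly 1.  Categories absent from the table are an error
    downstream, never silently defaulted.
    """

    entries: dict[str, float]
    habitat_labels: frozenset[str]

    def __post_init__(self) -> None:
        self.habitat_labels = frozenset(self.habitat_labels)
        for label, r in self.entries.items():
            if r < 1:
                raise ValueError(f"resistance for {label!r} is {r}; must be >= 1")
        for label in self.habitat_labels:
            if self.entries.get(label) != 1:
                raise ValueError(f"habitat category {label!r} must have resistance 1")

    def resistance(self, label: str) -> float:
        try:
            return self.entries[label]
        except KeyError:
            raise KeyError(
                f"no resistance entry for land-cover category {label!r}"
            ) from None

    def is_habitat(self, label: str) -> bool:
        return label in self.habitat_labels


@dataclass
class ResistanceSurface:
    """Per-cell movement resistance on the same grid as its source raster."""

    grid: np.ndarray
    cell_size: float
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("resistance grid must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if np.nanmin(self.grid) < 1:
            raise ValueError("resistance values must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def world_to_cell(self, x: float, y: float) -> tuple[int, int]:
        c = int(np.floor((x - self.origin[0]) / self.cell_size))
        r = int(np.floor((self.origin[1] - y) / self.cell_size))
        return r, c


@dataclass
class Feature:
    """One linear landscape feature: a polyline with a type and a width."""

    line: LineString
    feature_type: str
    width_m: float

    def __post_init__(self) -> None:
        if not isinstance(self.line, LineString):
            self.line = LineString(self.line)
        if self.width_m <= 0:
            raise ValueError("feature width must be positive")
        if len(self.line.coords) < 2 or self.line.length == 0:
            raise ValueError("feature polyline must have >= 2 distinct vertices")


@dataclass
class FeatureSet:
    """Collection of linear features (field edges, rivers, roads, tracks...)."""

    features: list[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def by_type(self, feature_type: str) -> "FeatureSet":
        return FeatureSet([f for f in self.features if f.feature_type == feature_type])


@dataclass
class HabitatPatchSet:
    """Connected components of habitat cells.

    ``labels`` holds a patch id per cell (0 = matrix / non-habitat);
    ``patch_areas`` is in hectares; ``visited_flags`` marks patches that
    contain at least one GPS fix (filled by the connectivity stage).
    """

    labels: np.ndarray
    patch_areas: dict[int, float]
    cell_size: float
    origin: tuple[float, float]
    visited_flags: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.visited_flags:
            self.visited_flags = {pid: False for pid in self.patch_areas}

    @property
    def n_patches(self) -> int:
        return len(self.patch_areas)

    def patch_ids(self) -> list[int]:
        return sorted(self.patch_areas)

    def visited_ids(self) -> list[int]:
        return sorted(pid for pid, v in self.visited_flags.items() if v)

    def mask(self, patch_id: int | None = None) -> np.ndarray:
        if patch_id is None:
            return self.labels > 0
        return self.labels == patch_id

    def world_to_cell(self, x: float, y: float) -> tuple[int, int]:
        c = int(np.floor((x - self.origin[0]) / self.cell_size))
        r = int(np.floor((self.origin[1] - y) / self.cell_size))
        return r, c


def _raster_bounds(lc: LandCoverRaster) -> tuple[float, float, float, float]:
    nr, nc = lc.grid.shape
    x0, y1 = lc.origin
    return x0, y1 - nr * lc.cell_size, x0 + nc * lc.cell_size, y1


def burn_linear_features(
    lc: LandCoverRaster,
    fs: FeatureSet,
    category_of: dict[str, str],
) -> LandCoverRaster:
    """Overwrite cells lying under linear features with the feature category.

    A cell is burned when its centre lies within ``width/2`` of the feature
    polyline (Euclidean distance in world metres).  Later features in the
    set overwrite earlier ones.  Features wholly outside the raster are
    clipped with a warning; the operation is idempotent.

    Parameters
    ----------
    category_of
        Maps feature type (e.g. ``"field edge"``) to a land-cover label.
        Labels absent from ``lc.category_names`` are added with a fresh code.
    """
    out = lc.copy()
    name_to_code = {v: k for k, v in out.category_names.items()}
    next_code = max(out.category_names, default=0) + 1
    xs, ys = lc.cell_centers()
    xmin, ymin, xmax, ymax = _raster_bounds(lc)

    for feat in fs:
        try:
            label = category_of[feat.feature_type]
        except KeyError:
            raise KeyError(
                f"no target category for feature type {feat.feature_type!r}"
            ) from None
        if label not in name_to_code:
            name_to_code[label] = next_code
            out.category_names[next_code] = label
            next_code += 1
        code = name_to_code[label]

        half = feat.width_m / 2.0
        bx0, by0, bx1, by1 = feat.line.bounds
        if bx1 < xmin - half or bx0 > xmax + half or by1 < ymin - half or by0 > ymax + half:
            warnings.warn(
                f"feature {feat.feature_type!r} lies outside the raster extent; clipped",
                stacklevel=2,
            )
            continue
        # restrict the per-cell distance test to the feature's bounding box
        cs = lc.cell_size
        c0 = max(0, int((bx0 - half - lc.origin[0]) / cs) - 1)
        c1 = min(lc.grid.shape[1], int((bx1 + half - lc.origin[0]) / cs) + 2)
        r0 = max(0, int((lc.origin[1] - by1 - half) / cs) - 1)
        r1 = min(lc.grid.shape[0], int((lc.origin[1] - by0 + half) / cs) + 2)
        if r0 >= r1 or c0 >= c1:
            warnings.warn(
                f"feature {feat.feature_type!r} lies outside the raster extent; clipped",
                stacklevel=2,
            )
            continue
        sub_x = xs[r0:r1, c0:c1]
        sub_y = ys[r0:r1, c0:c1]
        dist = _points_to_line_distance(sub_x.ravel(), sub_y.ravel(), feat.line)
        hit = (dist <= half).reshape(sub_x.shape)
        out.grid[r0:r1, c0:c1][hit] = code
    return out


def _points_to_line_distance(px: np.ndarray, py: np.ndarray, line: LineString) -> np.ndarray:
    """Vectorized distance from points to a polyline (min over segments)."""
    coords = np.asarray(line.coords)
    best = np.full(px.shape, np.inf)
    for (x1, y1), (x2, y2) in zip(coords[:-1], coords[1:]):
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        if seg2 == 0:
            d = np.hypot(px - x1, py - y1)
        else:
            t = np.clip(((px - x1) * dx + (py - y1) * dy) / seg2, 0.0, 1.0)
            d = np.hypot(px - (x1 + t * dx), py - (y1 + t * dy))
        np.minimum(best, d, out=best)
    return best


def build_resistance_surface(lc: LandCoverRaster, rt: ResistanceTable) -> ResistanceSurface:
    """Element-wise substitution of category code -> resistance value.

    Raises
    ------
    KeyError
        If any category present in the grid lacks a table entry (named in
        the message); no silent default is applied.
    """
    codes = np.unique(lc.grid)
    lut_size = int(codes.max()) + 1
    lut = np.full(lut_size, np.nan)
    for code in codes:
        label = lc.category_names[int(code)]
        lut[int(code)] = rt.resistance(label)  # KeyError names the label
    grid = lut[lc.grid]
    return ResistanceSurface(grid, lc.cell_size, lc.origin)


def label_habitat_patches(
    lc: LandCoverRaster,
    rt: ResistanceTable,
    connectivity: int = 8,
) -> HabitatPatchSet:
    """Label connected components of habitat cells.

    Habitat cells are those whose category label is in ``rt.habitat_labels``
    (woodland of any size).  Patch areas are reported in hectares
    (cell count x cell_size^2 / 10^4).
    """
    if not rt.habitat_labels:
        raise ValueError("resistance table declares no habitat categories")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    habitat_codes = [
        code
        for code, label in lc.category_names.items()
        if label in rt.habitat_labels
    ]
    habitat = np.isin(lc.grid, habitat_codes)
    if not habitat.any():
        warnings.warn("raster contains no habitat cells", stacklevel=2)
        return HabitatPatchSet(
            np.zeros(lc.grid.shape, dtype=int), {}, lc.cell_size, lc.origin
        )
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndimage.label(habitat, structure=structure)
    counts = np.bincount(labels.ravel())
    cell_ha = lc.cell_size**2 / 1e4
    areas = {pid: float(counts[pid]) * cell_ha for pid in range(1, n + 1)}
    return HabitatPatchSet(labels, areas, lc.cell_size, lc.origin)
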