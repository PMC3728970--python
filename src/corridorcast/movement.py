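"""From raw GPS fixes to dwell clusters, inter-patch movements and use data.

A collar records a fix nominally every 3 minutes.  While an animal sits in
a woodland the fixes pile up (high local point density); while it crosses
the matrix they string out.  A *movement* is a maximal run of consecutive
fixes between two dwell clusters: its first fix is the last fix inside the
origin cluster and its last fix is the first fix recorded inside the
destination cluster.  Fix-success bookkeeping follows the collar's nominal
interval: the expected fix count over a movement of ``duration_min``
minutes is ``duration_min / 3`` (reported rounded to the nearest integer),
and the success percentage is the recorded count against the unrounded
expectation, capped at 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .landscape import FeatureSet, HabitatPatchSet, LandCoverRaster

__all__ = [
    "GPSTrack",
    "ClusterLabeling",
    "Movement",
    "UseObservation",
    "point_density",
    "expected_fix_count",
    "fix_success_pct",
    "identify_clusters",
    "segment_movements",
    "movements_to_frame",
    "landcover_use",
    "nearest_distances",
]

NOMINAL_INTERVAL_S = 180.0
DEFAULT_DENSITY_RADIUS_M = 30.0
DEFAULT_MIN_DENSITY = 5


@dataclass
class GPSTrack:
    """Ordered, timestamped GPS fixes for one animal.

    ``times`` is seconds (float, monotone strictly increasing); ``xy`` is
    an (n, 2) array of world coordinates in metres.
    """

    animal_id: str
    times: np.ndarray
    xy: np.ndarray
    nominal_interval_s: float = NOMINAL_INTERVAL_S

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.times) != len(self.xy):
            raise ValueError("times and coordinates differ in length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.isfinite(self.xy).all():
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ClusterLabeling:
    """Per-fix cluster membership (0 = not clustered) and cluster->patch map."""

    labels: np.ndarray
    cluster_patch: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_patch)

    def cluster_span(self, cid: int) -> tuple[int, int]:
        """(first, last) fix index of a cluster."""
        idx = np.flatnonzero(self.labels == cid)
        return int(idx[0]), int(idx[-1])


@dataclass
class Movement:
    """One inter-cluster transit with its length and fix-success metrics."""

    animal_id: str
    movement_index: int
    fix_indices: tuple[int, int]  # inclusive range into the track
    origin_cluster: int
    destination_cluster: int
    euclidean_km: float
    path_km: float
    duration_min: float
    n_locations: int
    expected_locations: int
    success_pct: float


@dataclass
class UseObservation:
    """Per-fix habitat/feature context used by the distance statistics."""

    fix_index: int
    category: str
    dist_habitat_m: float
    dist_feature_m: float | None
    feature_type: str | None
    in_matrix: bool


def point_density(track: GPSTrack, radius_m: float = DEFAULT_DENSITY_RADIUS_M) -> np.ndarray:
    """Number of fixes (self included) within ``radius_m`` of each fix."""
    if radius_m <= 0:
        raise ValueError("density radius must be positive")
    tree = cKDTree(track.xy)
    return np.array([len(nb) for nb in tree.query_ball_point(track.xy, radius_m)])


def identify_clusters(
    track: GPSTrack,
    density: np.ndarray,
    min_density: int,
    patches: HabitatPatchSet,
) -> ClusterLabeling:
    """Maximal consecutive dense runs bound to habitat patches.

    A run of consecutive fixes with density >= ``min_density`` becomes a
    cluster when the majority of its fixes fall inside a single habitat
    patch (majority vote absorbs GPS scatter just outside the canopy); the
    cluster is bound to that patch.  Dense runs with no patch majority are
    left unclustered.
    """
    if min_density < 2:
        raise ValueError("min_density must be >= 2")
    density = np.asarray(density)
    dense = density >= min_density
    if not dense.any():
        warnings.warn("no fix reaches the density threshold; zero clusters", stacklevel=2)
        return ClusterLabeling(np.zeros(len(track), dtype=int), {})

    patch_of_fix = _patch_ids(track.xy, patches)
    labels = np.zeros(len(track), dtype=int)
    cluster_patch: dict[int, int] = {}
    cid = 0
    i = 0
    n = len(track)
    while i < n:
        if not dense[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and dense[j + 1]:
            j += 1
        run = patch_of_fix[i : j + 1]
        inside = run[run > 0]
        if inside.size:
            ids, counts = np.unique(inside, return_counts=True)
            best = ids[counts.argmax()]
            if counts.max() * 2 > run.size:  # strict majority of the run
                cid += 1
                labels[i : j + 1] = cid
                cluster_patch[cid] = int(best)
        i = j + 1
    return ClusterLabeling(labels, cluster_patch)


def _patch_ids(xy: np.ndarray, patches: HabitatPatchSet) -> np.ndarray:
    nr, nc = patches.labels.shape
    c = np.floor((xy[:, 0] - patches.origin[0]) / patches.cell_size).astype(int)
    r = np.floor((patches.origin[1] - xy[:, 1]) / patches.cell_size).astype(int)
    ok = (r >= 0) & (r < nr) & (c >= 0) & (c < nc)
    out = np.zeros(len(xy), dtype=int)
    out[ok] = patches.labels[r[ok], c[ok]]
    return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def expected_fix_count(duration_min: float, interval_min: float = 3.0) -> int:
    """Nominal number of fixes over a movement: round(duration / interval),
    half-up (a 127-minute movement at 3-minute fixes expects 42)."""
    return _round_half_up(duration_min / interval_min)


def fix_success_pct(n_locations: int, duration_min: float,
                    interval_min: float = 3.0) -> float:
    """Recorded fixes as a percentage of the unrounded nominal count,
    capped at 100 (durations that are not interval multiples can record
    one fix more than the nominal expectation)."""
    expected_exact = duration_min / interval_min
    if expected_exact <= 0:
        return 100.0
    return min(100.0, 100.0 * n_locations / expected_exact)


def segment_movements(track: GPSTrack, clusters: ClusterLabeling) -> list[Movement]:
    """One movement per consecutive cluster pair.

    The movement runs from the last fix of the origin cluster to the first
    fix of the destination cluster (inclusive).  ``expected_locations`` is
    the nominal fix count round(duration_min / interval_min); the success
    percentage uses the unrounded expectation and is capped at 100 (a
    short transit can record one fix more than the nominal count when its
    duration is not a multiple of the interval).
    """
    if clusters.n_clusters < 2:
        return []
    interval_min = track.nominal_interval_s / 60.0
    movements: list[Movement] = []
    cids = sorted(clusters.cluster_patch)
    for k, (ca, cb) in enumerate(zip(cids[:-1], cids[1:]), start=1):
        _, last_a = clusters.cluster_span(ca)
        first_b, _ = clusters.cluster_span(cb)
        i0, i1 = last_a, first_b
        seg = track.xy[i0 : i1 + 1]
        duration_min = (track.times[i1] - track.times[i0]) / 60.0
        n_loc = i1 - i0 + 1
        expected = expected_fix_count(duration_min, interval_min)
        success = fix_success_pct(n_loc, duration_min, interval_min)
        movements.append(
            Movement(
                animal_id=track.animal_id,
                movement_index=k,
                fix_indices=(i0, i1),
                origin_cluster=ca,
                destination_cluster=cb,
                euclidean_km=float(np.hypot(*(seg[-1] - seg[0]))) / 1000.0,
                path_km=float(np.sum(np.hypot(*np.diff(seg, axis=0).T))) / 1000.0,
                duration_min=float(duration_min),
                n_locations=n_loc,
                expected_locations=expected,
                success_pct=float(success),
            )
        )
    return movements


def movements_to_frame(movements: list[Movement]) -> pd.DataFrame:
    """Movement table with the standard reporting columns."""
    return pd.DataFrame(
        {
            "animal_id": [m.animal_id for m in movements],
            "movement": [m.movement_index for m in movements],
            "n_locations": [m.n_locations for m in movements],
            "expected_locations": [m.expected_locations for m in movements],
            "euclidean_km": [m.euclidean_km for m in movements],
            "path_km": [m.path_km for m in movements],
            "duration_min": [m.duration_min for m in movements],
            "success_pct": [m.success_pct for m in movements],
        }
    )


def landcover_use(
    fixes: np.ndarray,
    lc: LandCoverRaster,
    groups: dict[str, str] | None = None,
    region_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Observed fix counts per land-cover group vs area-proportional expectation.

    Parameters
    ----------
    fixes
        (n, 2) world coordinates; fixes outside the raster are excluded
        (logged via warning).
    groups
        Optional category label -> group label map (e.g. pooling road,
        path, road verge and track); unmapped categories keep their own
        label.
    region_mask
        Boolean grid restricting the availability calculation (default:
        the whole raster).

    Returns
    -------
    DataFrame indexed by group with columns ``observed`` and ``expected``
    (expected proportional to group area inside the region, scaled to the
    number of retained fixes).
    """
    fixes = np.asarray(fixes, dtype=float).reshape(-1, 2)
    nr, nc = lc.grid.shape
    c = np.floor((fixes[:, 0] - lc.origin[0]) / lc.cell_size).astype(int)
    r = np.floor((lc.origin[1] - fixes[:, 1]) / lc.cell_size).astype(int)
    ok = (r >= 0) & (r < nr) & (c >= 0) & (c < nc)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} fixes outside the raster were excluded", stacklevel=2)
    codes = lc.grid[r[ok], c[ok]]

    def group_of(code: int) -> str:
        label = lc.category_names[int(code)]
        return groups.get(label, label) if groups else label

    observed: dict[str, int] = {}
    for code in codes:
        g = group_of(code)
        observed[g] = observed.get(g, 0) + 1

    region = region_mask if region_mask is not None else np.ones_like(lc.grid, dtype=bool)
    area_counts: dict[str, int] = {}
    vals, counts = np.unique(lc.grid[region], return_counts=True)
    for code, cnt in zip(vals, counts):
        g = group_of(code)
        area_counts[g] = area_counts.get(g, 0) + int(cnt)
    all_groups = sorted(set(observed) | set(area_counts))
    total_area = sum(area_counts.values())
    n = int(ok.sum())
    frame = pd.DataFrame(
        {
            "observed": [observed.get(g, 0) for g in all_groups],
            "expected": [n * area_counts.get(g, 0) / total_area for g in all_groups],
        },
        index=pd.Index(all_groups, name="group"),
    )
    return frame


def nearest_distances(
    fixes: np.ndarray,
    lc: LandCoverRaster,
    patches: HabitatPatchSet,
    fs: FeatureSet,
) -> list[UseObservation]:
    """Distance from each fix to the nearest habitat cell and feature line.

    Habitat distance is measured to the nearest habitat cell centre
    (0 for fixes inside habitat), feature distance exactly to the nearest
    feature polyline with its type recorded.  With an empty feature set the
    feature fields are ``None`` (undefined), never zero.
    """
    fixes = np.asarray(fixes, dtype=float).reshape(-1, 2)
    habitat = patches.mask()
    rr, cc = np.nonzero(habitat)
    hab_xy = np.column_stack(
        [
            patches.origin[0] + (cc + 0.5) * patches.cell_size,
            patches.origin[1] - (rr + 0.5) * patches.cell_size,
        ]
    )
    tree = cKDTree(hab_xy) if len(hab_xy) else None
    patch_of_fix = _patch_ids(fixes, patches)

    from shapely.geometry import Point

    out: list[UseObservation] = []
    for i, (x, y) in enumerate(fixes):
        in_hab = patch_of_fix[i] > 0
        if in_hab:
            d_hab = 0.0
        elif tree is not None:
            d_hab = float(tree.query([x, y])[0])
        else:
            d_hab = np.inf
        d_feat: float | None = None
        ftype: str | None = None
        if len(fs):
            p = Point(x, y)
            best = np.inf
            for feat in fs:
                d = p.distance(feat.line)
                if d < best:
                    best, ftype = d, feat.feature_type
            d_feat = float(best)
        r, c = lc.world_to_cell(x, y)
        nr, nc_ = lc.grid.shape
        category = (
            lc.category_names[int(lc.grid[r, c])]
            if 0 <= r < nr and 0 <= c < nc_
            else "<outside>"
        )
        out.append(
            UseObservation(
                fix_index=i,
                category=category,
                dist_habitat_m=d_hab,
                dist_feature_m=d_feat,
                feature_type=ftype,
                in_matrix=not in_hab,
            )
        )
    return out
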