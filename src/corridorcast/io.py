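"""File formats: ESRI ASCII grids, GeoJSON features, CSV tables.

Rasters travel as single-band ESRI ASCII grids (integer category codes for
land cover, floats for resistance/cost surfaces, NoData for unreachable
cells).  Linear features travel as GeoJSON LineString/MultiLineString with
``{"type": ..., "width_m": ...}`` properties; paths and mask outlines are
written back as GeoJSON.  GPS fixes are CSV ``animal_id,timestamp,x,y``
with ISO-8601 timestamps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiLineString, mapping, shape

from .landscape import (
    Feature,
    FeatureSet,
    LandCoverRaster,
    ResistanceSurface,
    ResistanceTable,
)
from .movement import GPSTrack

__all__ = [
    "read_ascii_grid",
    "write_ascii_grid",
    "landcover_to_ascii",
    "landcover_from_ascii",
    "resistance_to_ascii",
    "read_features_geojson",
    "write_features_geojson",
    "write_paths_geojson",
    "write_mask_ascii",
    "read_resistance_table",
    "write_resistance_table",
    "read_fixes_csv",
    "write_fixes_csv",
]

NODATA = -9999


def read_ascii_grid(path) -> tuple[np.ndarray, float, tuple[float, float], float]:
    """Read an ESRI ASCII grid.

    Returns (grid, cell_size, origin, nodata) where origin is the world
    coordinate of the outer corner of the *top-left* cell.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        grid = np.loadtxt(fh)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    grid = grid.reshape(nrows, ncols)
    cs = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cs)
    return grid, cs, origin, header.get("nodata_value", NODATA)


def write_ascii_grid(path, grid: np.ndarray, cell_size: float,
                     origin: tuple[float, float], nodata: float = NODATA,
                     fmt: str = "%.6g") -> None:
    grid = np.asarray(grid)
    nrows, ncols = grid.shape
    out = np.where(np.isfinite(grid.astype(float)), grid, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin[0]:.6f}\n")
        fh.write(f"yllcorner {origin[1] - nrows * cell_size:.6f}\n")
        fh.write(f"cellsize {cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, out, fmt=fmt)


def landcover_to_ascii(lc: LandCoverRaster, path, names_path=None) -> None:
    """Write a land-cover raster; category names go to a JSON sidecar
    (default: ``<path>.names.json``)."""
    write_ascii_grid(path, lc.grid, lc.cell_size, lc.origin, fmt="%d")
    names_path = names_path or (str(path) + ".names.json")
    with open(names_path, "w") as fh:
        json.dump({str(k): v for k, v in lc.category_names.items()}, fh, indent=1)


def landcover_from_ascii(path, names_path=None) -> LandCoverRaster:
    grid, cs, origin, _ = read_ascii_grid(path)
    names_path = names_path or (str(path) + ".names.json")
    with open(names_path) as fh:
        names = {int(k): v for k, v in json.load(fh).items()}
    return LandCoverRaster(grid.astype(int), cs, origin, names)


def resistance_to_ascii(rs: ResistanceSurface, path) -> None:
    write_ascii_grid(path, rs.grid, rs.cell_size, rs.origin)


def write_mask_ascii(mask_obj, path) -> None:
    """Binary mask (1 = inside the model) as an ASCII grid."""
    write_ascii_grid(path, mask_obj.mask.astype(int), mask_obj.cell_size,
                     mask_obj.origin, fmt="%d")


def read_features_geojson(path) -> FeatureSet:
    with open(path) as fh:
        gj = json.load(fh)
    feats: list[Feature] = []
    for f in gj.get("features", []):
        geom = shape(f["geometry"])
        props = f.get("properties") or {}
        ftype = props.get("type", "feature")
        width = float(props.get("width_m", 4.0))
        lines = geom.geoms if isinstance(geom, MultiLineString) else [geom]
        for line in lines:
            feats.append(Feature(LineString(line), ftype, width))
    return FeatureSet(feats)


def write_features_geojson(fs: FeatureSet, path) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f.line),
                "properties": {"type": f.feature_type, "width_m": f.width_m},
            }
            for f in fs
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def write_paths_geojson(paths, path) -> None:
    """Least-cost paths as LineStrings with total_cost / length_m properties."""
    feats = []
    for p in paths:
        if len(p.vertices) < 2:
            continue
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(LineString(p.vertices)),
                "properties": {"total_cost": p.total_cost, "length_m": p.length_m},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_resistance_table(path) -> ResistanceTable:
    """CSV with columns ``category,resistance,is_habitat``."""
    frame = pd.read_csv(path)
    entries = dict(zip(frame["category"], frame["resistance"].astype(float)))
    habitat = frozenset(frame.loc[frame["is_habitat"].astype(bool), "category"])
    return ResistanceTable(entries, habitat)


def write_resistance_table(rt: ResistanceTable, path) -> None:
    frame = pd.DataFrame(
        {
            "category": list(rt.entries),
            "resistance": [rt.entries[c] for c in rt.entries],
            "is_habitat": [c in rt.habitat_labels for c in rt.entries],
        }
    )
    frame.to_csv(path, index=False)


def read_fixes_csv(path) -> list[GPSTrack]:
    """CSV ``animal_id,timestamp,x,y`` -> one GPSTrack per animal (sorted
    by time within animal)."""
    frame = pd.read_csv(path)
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    tracks = []
    for aid, sub in frame.groupby("animal_id", sort=True):
        sub = sub.sort_values("timestamp")
        times = sub["timestamp"].astype("int64").to_numpy() / 1e9
        tracks.append(GPSTrack(str(aid), times, sub[["x", "y"]].to_numpy()))
    return tracks


def write_fixes_csv(tracks: list[GPSTrack], path) -> None:
    rows = []
    for t in tracks:
        ts = pd.to_datetime((t.times * 1e9).astype("int64"))
        for stamp, (x, y) in zip(ts, t.xy):
            rows.append({"animal_id": t.animal_id, "timestamp": stamp.isoformat(),
                         "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def default_resistance_table_path() -> Path:
    return Path(__file__).parent / "data" / "resistance_table.csv"
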