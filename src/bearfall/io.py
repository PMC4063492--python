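"""Plain-text I/O: GeoJSON feature collections, ESRI ASCII grids, fix/cone CSVs.

All geometry is exchanged in a projected CRS in meters.  GeoJSON files written
here carry a ``crs_note`` in the top-level collection so downstream readers can
refuse geographic coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

FIX_COLUMNS = ["bear_id", "sex", "year", "timestamp", "success", "x", "y"]


def write_geojson(geoms, path, properties=None, crs_note="projected-meters"):
    """Write geometries (+ optional per-feature property dicts) as GeoJSON."""
    geoms = list(geoms)
    if properties is None:
        properties = [{} for _ in geoms]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": dict(p)}
        for g, p in zip(geoms, properties)
    ]
    doc = {"type": "FeatureCollection", "crs_note": crs_note, "features": features}
    Path(path).write_text(json.dumps(doc))


def read_geojson(path):
    """Read a GeoJSON FeatureCollection -> (list of shapely geoms, list of dicts)."""
    doc = json.loads(Path(path).read_text())
    geoms, props = [], []
    for feat in doc.get("features", []):
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties") or {})
    return geoms, props


def write_ascii_grid(array, x0, y0, cellsize, path, nodata=-9999.0):
    """Write a 2D array (row 0 = southernmost) as an ESRI ASCII grid."""
    arr = np.asarray(array, dtype=float)
    nrows, ncols = arr.shape
    out = arr.copy()
    out[~np.isfinite(out)] = nodata
    header = (
        f"ncols {ncols}\nnrows {nrows}\nxllcorner {x0}\nyllcorner {y0}\n"
        f"cellsize {cellsize}\nNODATA_value {nodata}\n"
    )
    # ESRI ASCII stores the top row first
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in out[::-1])
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid -> (array row0=south, x0, y0, cellsize); NODATA -> nan."""
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        k, v = lines[i].split()
        hdr[k.lower()] = float(v)
        i += 1
    rows = [np.array(ln.split(), dtype=float) for ln in lines[i:] if ln.strip()]
    arr = np.vstack(rows)[::-1]
    nodata = hdr.get("nodata_value")
    if nodata is not None:
        arr[arr == nodata] = np.nan
    return arr, hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"]


def write_fixes_csv(seasons, path, include_truth=False):
    """Write BearSeason fix attempts as the canonical fixes CSV."""
    rows = []
    for s in seasons:
        for a in s.attempts:
            row = {
                "bear_id": s.bear_id,
                "sex": s.sex,
                "year": s.year,
                "timestamp": a.timestamp.isoformat(),
                "success": int(a.success),
                "x": a.x if a.success else "",
                "y": a.y if a.success else "",
            }
            if include_truth:
                row.update(
                    true_x=a.true_x, true_y=a.true_y,
                    true_in_wbp=int(bool(a.true_in_wbp)),
                    true_in_secure=int(bool(a.true_in_secure)),
                )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fixes_csv(path):
    """Read a fixes CSV back into a list of BearSeason objects."""
    from .habitat_use import BearSeason, FixAttempt

    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    seasons = []
    for (bear_id, sex, year), grp in df.groupby(["bear_id", "sex", "year"], sort=True):
        grp = grp.sort_values("timestamp")
        attempts = [
            FixAttempt(
                bear_id=bear_id,
                timestamp=r.timestamp.to_pydatetime(),
                success=bool(r.success),
                x=float(r.x) if r.success and pd.notna(r.x) else None,
                y=float(r.y) if r.success and pd.notna(r.y) else None,
            )
            for r in grp.itertuples()
        ]
        seasons.append(BearSeason(bear_id=str(bear_id), sex=sex, year=int(year),
                                  attempts=attempts))
    return seasons


def geometry_or_empty(geoms):
    """Collect an iterable of geometries into one (possibly empty) geometry."""
    import shapely

    geoms = [g for g in geoms if isinstance(g, BaseGeometry) and not g.is_empty]
    if not geoms:
        return shapely.geometry.Polygon()
    return shapely.union_all(geoms)
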