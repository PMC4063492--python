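"""Binary habitat layers (whitebark pine, secure habitat) and the impact grid.

Secure habitat follows the interagency definition used for Yellowstone grizzly
bears: any patch at least 4.05 ha in size lying 500 m or more from a motorized
road.  The impact grid scores 250-m cells of high-canopy whitebark pine with
the proportional NDVI decline relative to a baseline year; cells outside
high-canopy whitebark pine are unscored.

Conventions
-----------
* All coordinates are projected meters.  Geographic-looking inputs (every
  |coordinate| < 360) are rejected at ingest.
* Point-in-polygon uses ``covers`` semantics: boundary points are inside.
* Grid-cell membership is decided by the cell center, matching the MODIS
  250-m pixel convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.geometry.base import BaseGeometry

SECURE_BUFFER_M = 500.0
SECURE_MIN_PATCH_HA = 4.05


def _as_geometry(layer):
    if isinstance(layer, BaseGeometry):
        return layer
    if isinstance(layer, SecureLayer):
        return layer.geometry
    return shapely.union_all(list(layer)) if layer else Polygon()


def check_projected(geom):
    """Reject geometry that looks like lon/lat rather than projected meters."""
    if geom.is_empty:
        return
    minx, miny, maxx, maxy = geom.bounds
    if max(abs(minx), abs(miny), abs(maxx), abs(maxy)) < 360.0:
        raise ValueError(
            "coordinates look geographic (all |values| < 360); "
            "a projected CRS in meters is required"
        )


@dataclass
class SecureLayer:
    """Secure-habitat polygons: >= min_patch_ha, >= buffer_m from any road."""

    polygons: list = field(default_factory=list)
    buffer_m: float = SECURE_BUFFER_M
    min_patch_ha: float = SECURE_MIN_PATCH_HA

    @property
    def geometry(self):
        return shapely.union_all(self.polygons) if self.polygons else Polygon()

    @property
    def area_km2(self):
        return self.geometry.area / 1e6


def derive_secure(roads, extent, buffer_m=SECURE_BUFFER_M,
                  min_patch_ha=SECURE_MIN_PATCH_HA):
    """Secure habitat = extent minus the road buffer, small patches dropped.

    Parameters
    ----------
    roads : iterable of LineString (or a single geometry); may be empty.
    extent : shapely Polygon, or (xmin, ymin, xmax, ymax).
    """
    if not isinstance(extent, BaseGeometry):
        extent = box(*extent)
    if extent.is_empty or extent.area == 0:
        raise ValueError("empty extent")
    road_geom = _as_geometry(list(roads) if not isinstance(roads, BaseGeometry) else roads)
    if road_geom.is_empty:
        secure = extent
    else:
        secure = extent.difference(road_geom.buffer(buffer_m))
    parts = (
        list(secure.geoms) if secure.geom_type == "MultiPolygon"
        else ([] if secure.is_empty else [secure])
    )
    kept = [p for p in parts if p.area >= min_patch_ha * 1e4]
    return SecureLayer(polygons=kept, buffer_m=buffer_m, min_patch_ha=min_patch_ha)


def classify_point(layer, x, y):
    """True iff (x, y) is within or on the boundary of the layer."""
    if not np.isfinite(x) or not np.isfinite(y):
        raise ValueError("non-finite coordinates")
    geom = _as_geometry(layer)
    if geom.is_empty:
        return False
    return bool(shapely.intersects_xy(geom, x, y))


def classify_points(layer, xs, ys):
    """Vectorized classify_point -> boolean array."""
    geom = _as_geometry(layer)
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if geom.is_empty:
        return np.zeros(xs.shape, dtype=bool)
    return shapely.intersects_xy(geom, xs, ys)


@dataclass
class ImpactSurface:
    """250-m grid of proportional NDVI decline over high-canopy WBP cells.

    ``delta`` is NaN on unscored cells (non-WBP or canopy < 50%).  Row 0 is the
    southernmost row; cell (i, j) has center
    (x0 + (j + 0.5) * cellsize, y0 + (i + 0.5) * cellsize).
    """

    x0: float
    y0: float
    cellsize: float
    delta: np.ndarray       # float, NaN where unscored
    wbp: np.ndarray         # bool
    canopy_ge_50: np.ndarray  # bool

    def __post_init__(self):
        scored = self.wbp & self.canopy_ge_50
        bad = np.isfinite(self.delta) & ~scored
        if bad.any():
            raise ValueError("delta_ndvi defined on unscored cells")
        vals = self.delta[np.isfinite(self.delta)]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("delta_ndvi outside [0, 1]")

    @property
    def shape(self):
        return self.delta.shape

    def cell_centers(self):
        nr, nc = self.delta.shape
        cx = self.x0 + (np.arange(nc) + 0.5) * self.cellsize
        cy = self.y0 + (np.arange(nr) + 0.5) * self.cellsize
        return np.meshgrid(cx, cy)

    def mean_scored_delta(self):
        vals = self.delta[np.isfinite(self.delta)]
        return float(vals.mean()) if vals.size else None


def mean_impact(surface, polygon):
    """Mean delta-NDVI over scored cells whose centers fall in the polygon.

    Cells are equal-area so the area-weighted mean is the simple mean of the
    member cells.  Returns ``None`` when no scored cell center lies in the
    polygon (distinct from a true mean of 0).
    """
    gx, gy = surface.cell_centers()
    scored = np.isfinite(surface.delta)
    if not scored.any():
        return None
    inside = shapely.intersects_xy(polygon, gx[scored], gy[scored])
    if not inside.any():
        return None
    return float(surface.delta[scored][inside].mean())
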