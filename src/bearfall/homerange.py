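"""100% adaptive local convex hull (a-LoCoH) fall home ranges.

For each location ("root point") a local set is formed from the root plus its
nearest neighbors, added in order of increasing distance while the cumulative
sum of neighbor distances stays within the adaptive parameter *a*.  The 100%
isopleth is the union of the convex hulls of all local sets, so every input
location is covered.  The default *a* is 2 x the maximum pairwise distance
between locations; when that produces "orphaned holes" (interior rings in the
union), the multiplier is searched outward from 2.0 in 0.1 steps within
[1.0, 2.4] and the nearest succeeding value is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, MultiPoint, Point

MULTIPLIER_DEFAULT = 2.0
MULTIPLIER_RANGE = (1.0, 2.4)
MULTIPLIER_STEP = 0.1
_DEGENERATE_BUFFER_M = 1.0


class ALoCoHError(ValueError):
    """Home-range construction failed (degenerate input or orphaned holes)."""


class OrphanedHolesError(ALoCoHError):
    """The hull union contains interior rings, the a-LoCoH failure mode."""

    def __init__(self, a_value, n_holes):
        self.a_value = a_value
        self.n_holes = n_holes
        super().__init__(
            f"a-LoCoH union at a={a_value:.1f} m has {n_holes} interior ring(s)"
        )


@dataclass
class FallRange:
    """An a-LoCoH 100% isopleth with its selection metadata.

    ``availability`` maps habitat label -> proportion of the range covered;
    labels come in WBP / non-WBP (summing to 1) and secure.
    """

    polygons: object            # shapely (Multi)Polygon union
    a_value: float
    multiplier: float
    area_km2: float
    availability: dict = field(default_factory=dict)
    mean_delta_ndvi: float | None = None
    hull_areas_sorted: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


def _unique_points(points):
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    return pts, uniq, inverse


def max_pairwise_distance(points):
    """Exact maximum Euclidean distance between any two locations.

    Computed on convex-hull vertices (the diameter is attained there), with a
    dense fallback for degenerate hulls.
    """
    pts, uniq, _ = _unique_points(points)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct points")
    cand = uniq
    if len(uniq) > 50:
        try:
            from scipy.spatial import ConvexHull

            cand = uniq[ConvexHull(uniq).vertices]
        except Exception:  # collinear etc. -> dense pairing below
            cand = uniq
    d2 = ((cand[:, None, :] - cand[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _is_collinear(uniq):
    if len(uniq) < 3:
        return True
    v = uniq - uniq[0]
    cross = v[:, 0][:, None] * v[:, 1][None, :] - v[:, 1][:, None] * v[:, 0][None, :]
    return bool(np.allclose(cross, 0.0))


def _local_hull(members):
    """Convex hull of a local set; degenerate sets buffered by 1 m."""
    if len(members) >= 3:
        hull = MultiPoint(members).convex_hull
        if hull.geom_type == "Polygon":
            return hull, False
    if len(members) == 1:
        return Point(members[0]).buffer(_DEGENERATE_BUFFER_M), True
    geom = LineString([members[0], members[-1]]) if len(members) == 2 else \
        MultiPoint(members).convex_hull
    return geom.buffer(_DEGENERATE_BUFFER_M), True


def build_alocoh(points, a_value, allow_holes=False):
    """Build the 100% a-LoCoH isopleth for one bear-season.

    Raises :class:`OrphanedHolesError` when the union has interior rings
    (unless ``allow_holes``, in which case the hole count is recorded in the
    diagnostics instead) and :class:`ALoCoHError` on degenerate input.
    Duplicate coordinates are collapsed before hull building and all original
    points are still covered (a duplicate shares its representative's hulls).
    """
    if a_value <= 0:
        raise ValueError("a_value must be positive")
    pts, uniq, _ = _unique_points(points)
    if _is_collinear(uniq):
        raise ALoCoHError("points are collinear or fewer than 3 distinct points")

    n = len(uniq)
    # distances from each root to all unique points; stable sort breaks
    # neighbor-distance ties by point index for determinism
    d = np.sqrt(((uniq[:, None, :] - uniq[None, :, :]) ** 2).sum(-1))
    hulls = []
    n_degenerate = 0
    for i in range(n):
        order = np.argsort(d[i], kind="stable")
        cum = np.cumsum(d[i][order])  # order[0] is the root itself (distance 0)
        k = int(np.searchsorted(cum, a_value, side="right"))
        members = uniq[order[:max(k, 1)]]
        hull, degen = _local_hull(members)
        n_degenerate += degen
        hulls.append(hull)

    union = shapely.union_all(hulls)
    polys = list(union.geoms) if union.geom_type == "MultiPolygon" else [union]
    n_holes = sum(len(p.interiors) for p in polys if p.geom_type == "Polygon")
    if n_holes and not allow_holes:
        raise OrphanedHolesError(a_value, n_holes)

    areas = np.sort([h.area for h in hulls])
    return FallRange(
        polygons=union,
        a_value=float(a_value),
        multiplier=float("nan"),
        area_km2=union.area / 1e6,
        hull_areas_sorted=areas,
        diagnostics={"n_points": len(pts), "n_unique": n,
                     "n_degenerate_hulls": n_degenerate, "n_holes": n_holes},
    )


def _multiplier_sequence():
    lo, hi = MULTIPLIER_RANGE
    seq = [MULTIPLIER_DEFAULT]
    step = 1
    while True:
        lower = MULTIPLIER_DEFAULT - step * MULTIPLIER_STEP
        upper = MULTIPLIER_DEFAULT + step * MULTIPLIER_STEP
        added = False
        if lower >= lo - 1e-9:
            seq.append(round(lower, 1))
            added = True
        if upper <= hi + 1e-9:
            seq.append(round(upper, 1))
            added = True
        if not added:
            return seq
        step += 1


def select_a(points):
    """Choose the adaptive parameter: a = multiplier x max pairwise distance.

    Multiplier 2.0 is tried first; on failure the search alternates
    1.9, 2.1, 1.8, 2.2, ... within [1.0, 2.4].
    """
    try:
        dmax = max_pairwise_distance(points)
    except ValueError as exc:
        raise ALoCoHError(str(exc)) from exc
    if dmax == 0:
        raise ALoCoHError("all points identical")
    failures = []
    for mult in _multiplier_sequence():
        a = mult * dmax
        try:
            build_alocoh(points, a)
        except OrphanedHolesError as exc:
            failures.append((mult, str(exc)))
            continue
        return a, mult
    raise ALoCoHError(
        f"no multiplier in [{MULTIPLIER_RANGE[0]}, {MULTIPLIER_RANGE[1]}] "
        f"succeeded; failures: {failures}"
    )


def fit_fall_range(points, fallback_with_holes=False):
    """select_a + build_alocoh in one call, recording the multiplier used.

    When every multiplier in the search range produces orphaned holes and
    ``fallback_with_holes`` is set, the default-multiplier construction is
    returned with its holes retained and counted in the diagnostics, instead
    of raising.  Degenerate inputs always raise.
    """
    try:
        a, mult = select_a(points)
    except ALoCoHError:
        if not fallback_with_holes:
            raise
        dmax = max_pairwise_distance(points)
        if dmax == 0:
            raise
        mult = MULTIPLIER_DEFAULT
        a = mult * dmax
        rng = build_alocoh(points, a, allow_holes=True)
        rng.multiplier = mult
        rng.diagnostics["holes_retained"] = True
        return rng
    rng = build_alocoh(points, a)
    rng.multiplier = mult
    return rng


def availability(fall_range, layer):
    """Proportion of the range covered by a habitat layer, in [0, 1]."""
    from .layers import _as_geometry

    range_geom = fall_range.polygons if isinstance(fall_range, FallRange) else fall_range
    if range_geom.area == 0:
        raise ValueError("zero-area range")
    layer_geom = _as_geometry(layer)
    if layer_geom.is_empty:
        return 0.0
    return float(range_geom.intersection(layer_geom).area / range_geom.area)
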