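"""Synthetic landscapes, impact surfaces, cone series, and GPS bear tracks.

Everything downstream (home ranges, selectivity, timing, movement, trend
models) is exercised against data from this module, so each generator exposes
the ground truth it was programmed with.

The movement model is a discrete-time Metropolis random walk on a 250-m raster
grid.  Habitat preference enters as a log-odds term in the step-acceptance
probability, which makes the walk's stationary distribution over its local
window proportional to exp(s_wbp * wbp + s_sec * secure).  With local WBP
availability p, the stationary proportion of time in WBP is

    U* = sigmoid(logit(p) + s_wbp)

and because the Manly-Chesson index equals sigmoid(logit(U) - logit(A)), the
walk's target MC index is simply sigmoid(s_wbp) -- independent of local
availability.  ``strength_for_target_mc`` inverts this, so cohorts can be
programmed with an exact selectivity trajectory (e.g., a linear decline from
0.69 to 0.48 across study years).

Randomness: every public generator takes one integer seed; independent streams
are split with numpy ``SeedSequence([seed, stream_id])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon, box

from .habitat_use import BearSeason, FixAttempt, season_window
from .layers import ImpactSurface, classify_points, derive_secure

CELLSIZE_M = 250.0
SUBSTEPS_PER_DAY = 48          # walk resolution, independent of fix schedule
CANOPY_FRACTION = 0.8          # share of WBP cells with >= 50% canopy
FIX_JITTER_M = 100.0
_STREAM_WBP, _STREAM_ROADS, _STREAM_CANOPY, _STREAM_NOISE = 11, 12, 101, 102


def _rng(seed, stream):
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def logit(p):
    return float(np.log(p / (1 - p)))


def sigmoid(x):
    return float(1 / (1 + np.exp(-x)))


def strength_for_target_mc(target_mc):
    """Log-odds habitat bias whose stationary MC index equals ``target_mc``."""
    if not 0 < target_mc < 1:
        raise ValueError("target MC must be in (0, 1)")
    return logit(target_mc)


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

@dataclass
class Landscape:
    """WBP patches, roads and park polygons over a rectangular extent (meters)."""

    wbp_polygons: list
    roads: list
    park_polygons: list
    extent: Polygon
    crs_note: str = "synthetic-projected-meters"

    @property
    def wbp_geometry(self):
        if not hasattr(self, "_wbp_geometry"):
            self._wbp_geometry = (
                shapely.union_all(self.wbp_polygons) if self.wbp_polygons else Polygon()
            )
        return self._wbp_geometry

    @property
    def secure_layer(self):
        if not hasattr(self, "_secure_layer"):
            self._secure_layer = derive_secure(self.roads, self.extent)
        return self._secure_layer

    @property
    def wbp_fraction(self):
        return self.wbp_geometry.area / self.extent.area


def generate_landscape(extent_km, wbp_fraction, n_roads, seed):
    """Random landscape with a target WBP area fraction (realized within 0.05).

    WBP habitat is laid down as overlapping round patches until the clipped
    union reaches the target fraction; roads are jittered transects across the
    extent; one rectangular park occupies a corner.
    """
    w_km, h_km = extent_km
    if w_km <= 0 or h_km <= 0:
        raise ValueError("extent must be positive")
    if not 0 <= wbp_fraction < 0.8:
        raise ValueError("wbp_fraction must be in [0, 0.8)")
    W, H = w_km * 1000.0, h_km * 1000.0
    extent = box(0.0, 0.0, W, H)

    rng = _rng(seed, _STREAM_WBP)
    patches = []
    union = Polygon()
    # patch radius ~ 4% of the extent diagonal scale keeps each increment small
    r0 = 0.04 * np.sqrt(W * H)
    while wbp_fraction > 0 and union.area / extent.area < wbp_fraction:
        cx, cy = rng.uniform(0, W), rng.uniform(0, H)
        r = r0 * rng.uniform(0.6, 1.4)
        patch = Point(cx, cy).buffer(r, quad_segs=8).intersection(extent)
        patches.append(patch)
        union = shapely.union_all([union, patch])
    wbp_polys = (
        list(union.geoms) if union.geom_type == "MultiPolygon"
        else ([] if union.is_empty else [union])
    )

    rrng = _rng(seed, _STREAM_ROADS)
    roads = []
    for _ in range(int(n_roads)):
        if rrng.random() < 0.5:  # west-east
            ys = rrng.uniform(0.1 * H, 0.9 * H, size=4)
            xs = np.linspace(0, W, 4)
        else:                    # south-north
            xs = rrng.uniform(0.1 * W, 0.9 * W, size=4)
            ys = np.linspace(0, H, 4)
        roads.append(LineString(np.column_stack([xs, ys])))

    park = box(0.0, 0.6 * H, 0.45 * W, H)  # north-west corner park
    return Landscape(wbp_polygons=wbp_polys, roads=roads,
                     park_polygons=[park], extent=extent)


# ---------------------------------------------------------------------------
# Impact surface
# ---------------------------------------------------------------------------

def generate_impact_surface(landscape, year, baseline_year, severity_per_year=0.01,
                            seed=0):
    """Delta-NDVI grid for one year of cumulative canopy decline.

    Each scored cell accumulates ``severity_per_year x (year - baseline)`` of
    proportional NDVI decline, modulated by a fixed per-cell susceptibility
    drawn once from the seed (Uniform(0.4, 1.0)), so the surface is identical
    across calls and grows monotonically with year.
    """
    if year < baseline_year:
        raise ValueError("year must be >= baseline_year")
    x0, y0, x1, y1 = landscape.extent.bounds
    nc = max(1, int(np.ceil((x1 - x0) / CELLSIZE_M)))
    nr = max(1, int(np.ceil((y1 - y0) / CELLSIZE_M)))
    cx = x0 + (np.arange(nc) + 0.5) * CELLSIZE_M
    cy = y0 + (np.arange(nr) + 0.5) * CELLSIZE_M
    gx, gy = np.meshgrid(cx, cy)

    wbp_geom = landscape.wbp_geometry
    wbp = (classify_points(wbp_geom, gx.ravel(), gy.ravel()).reshape(nr, nc)
           if not wbp_geom.is_empty else np.zeros((nr, nc), dtype=bool))
    canopy = _rng(seed, _STREAM_CANOPY).random((nr, nc)) < CANOPY_FRACTION
    scored = wbp & canopy
    suscept = _rng(seed, _STREAM_NOISE).uniform(0.4, 1.0, size=(nr, nc))
    delta = np.full((nr, nc), np.nan)
    delta[scored] = np.clip(
        severity_per_year * (year - baseline_year) * suscept[scored], 0.0, 1.0
    )
    return ImpactSurface(x0=x0, y0=y0, cellsize=CELLSIZE_M, delta=delta,
                         wbp=wbp, canopy_ge_50=canopy)


# ---------------------------------------------------------------------------
# Cone production series
# ---------------------------------------------------------------------------

@dataclass
class ConeRecord:
    year: int
    median_cones: float
    rating: str                 # "good" | "poor"
    prop_trees_alive: float


def simulate_cone_series(years, seed):
    """Masting-style cone series: good and poor years alternate strongly.

    A two-state regime chain (switch probability 0.8) draws high counts
    (8-22 cones/tree) in good regimes and low counts (0-2) in poor ones;
    ratings are then assigned with :func:`bearfall.models.classify_cone_year`.
    The proportion of live trees declines over the series.
    """
    from .models import classify_cone_year

    years = list(years)
    if len(years) < 2:
        raise ValueError("need >= 2 years")
    rng = _rng(seed, 21)
    state = rng.random() < 0.5
    counts = []
    for _ in years:
        counts.append(round(float(rng.uniform(8, 22)), 1) if state
                      else round(float(rng.uniform(0, 2)), 1))
        if rng.random() < 0.8:
            state = not state
    ratings = classify_cone_year(list(zip(years, counts)))
    alive = np.clip(1.0 - 0.07 * np.arange(len(years)), 0.25, 1.0)
    return [
        ConeRecord(year=y, median_cones=c, rating=r, prop_trees_alive=float(a))
        for y, c, r, a in zip(years, counts, ratings, alive)
    ]


# ---------------------------------------------------------------------------
# Bear track simulation
# ---------------------------------------------------------------------------

@dataclass
class SimBearConfig:
    """Ground-truth parameters for one simulated bear-season."""

    bear_id: str
    sex: str                        # "F" | "M"
    year: int
    wbp_selection_strength: float = 0.0      # log-odds bias toward WBP cells
    secure_selection_strength: float = 0.0
    step_scale_km: float = 0.25
    fixes_per_day: int = 24
    fix_success_base: float = 1.0
    fix_success_wbp_penalty: float = 0.0
    range_radius_km: float = 8.0
    seed: int = 0
    allow_custom_season: bool = False

    def __post_init__(self):
        if self.fixes_per_day < 1:
            raise ValueError("fixes_per_day must be >= 1")
        if not 0 < self.fix_success_base <= 1:
            raise ValueError("fix success base must be in (0, 1]")
        if not 0 <= self.fix_success_wbp_penalty < 1:
            raise ValueError("fix success penalty must be in [0, 1)")


@dataclass
class LandscapeGrid:
    """Rasterized habitat flags at the walk resolution (cell centers)."""

    x0: float
    y0: float
    cellsize: float
    wbp: np.ndarray
    secure: np.ndarray


def build_grid(landscape, cellsize=CELLSIZE_M):
    x0, y0, x1, y1 = landscape.extent.bounds
    nc = max(1, int(np.ceil((x1 - x0) / cellsize)))
    nr = max(1, int(np.ceil((y1 - y0) / cellsize)))
    cx = x0 + (np.arange(nc) + 0.5) * cellsize
    cy = y0 + (np.arange(nr) + 0.5) * cellsize
    gx, gy = np.meshgrid(cx, cy)
    wbp_geom = landscape.wbp_geometry
    wbp = (classify_points(wbp_geom, gx.ravel(), gy.ravel()).reshape(nr, nc)
           if not wbp_geom.is_empty else np.zeros((nr, nc), dtype=bool))
    secure = classify_points(landscape.secure_layer, gx.ravel(), gy.ravel()).reshape(nr, nc)
    return LandscapeGrid(x0=x0, y0=y0, cellsize=cellsize, wbp=wbp, secure=secure)


def simulate_bear_track(landscape, config, season=None, grid=None):
    """Simulate one bear's fall season of scheduled GPS fix attempts.

    The walk runs at :data:`SUBSTEPS_PER_DAY` Metropolis steps per day inside
    a square window around a random home center; fixes are sampled from the
    walk at the configured schedule (47 days x fixes_per_day attempts).  Fix
    success is Bernoulli with probability base x (1 - penalty x wbp), the
    canopy-driven GPS bias.  Failed attempts still record the true location
    and habitat so weighting methods can be validated against ground truth.
    """
    window = season_window(config.year)
    if season is not None and tuple(season) != window and not config.allow_custom_season:
        raise ValueError(
            f"season must be the 47-day window {window}; "
            "set allow_custom_season to override"
        )
    start_day, end_day = (season if (season is not None and config.allow_custom_season)
                          else window)
    n_days = (end_day - start_day).days + 1

    if grid is None:
        grid = build_grid(landscape)
    nr, nc = grid.wbp.shape
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed)]))

    radius_cells = max(2, int(round(config.range_radius_km * 1000 / grid.cellsize)))
    ci = int(rng.integers(0, nr))
    cj = int(rng.integers(0, nc))
    i0, i1 = max(0, ci - radius_cells), min(nr, ci + radius_cells + 1)
    j0, j1 = max(0, cj - radius_cells), min(nc, cj + radius_cells + 1)
    wwbp = grid.wbp[i0:i1, j0:j1]
    wsec = grid.secure[i0:i1, j0:j1]
    logw = (config.wbp_selection_strength * wwbp
            + config.secure_selection_strength * wsec)
    weights = np.exp(logw - logw.max())
    p_wbp = float(wwbp.mean())
    p_sec = float(wsec.mean())

    # initial cell drawn from the stationary distribution: no burn-in needed
    flat = weights.ravel() / weights.sum()
    start = int(rng.choice(flat.size, p=flat))
    wi, wj = divmod(start, wwbp.shape[1])

    n_steps = n_days * SUBSTEPS_PER_DAY
    R = max(1, int(round(config.step_scale_km * 1000 / grid.cellsize)))
    dis = rng.integers(-R, R + 1, size=n_steps)
    djs = rng.integers(-R, R + 1, size=n_steps)
    us = rng.random(n_steps)
    h, w = wwbp.shape
    path_i = np.empty(n_steps, dtype=np.int32)
    path_j = np.empty(n_steps, dtype=np.int32)
    lw = logw  # local alias
    cur_lw = lw[wi, wj]
    for t in range(n_steps):
        ni, nj = wi + dis[t], wj + djs[t]
        if 0 <= ni < h and 0 <= nj < w:
            new_lw = lw[ni, nj]
            if new_lw >= cur_lw or us[t] < np.exp(new_lw - cur_lw):
                wi, wj, cur_lw = ni, nj, new_lw
        path_i[t] = wi
        path_j[t] = wj

    # fix schedule: evenly spaced within each day
    fpd = config.fixes_per_day
    offsets = (np.arange(fpd) * SUBSTEPS_PER_DAY) // fpd
    step_idx = (np.arange(n_days)[:, None] * SUBSTEPS_PER_DAY + offsets[None, :]).ravel()
    n_att = step_idx.size

    gi = path_i[step_idx] + i0
    gj = path_j[step_idx] + j0
    jit = rng.uniform(-FIX_JITTER_M, FIX_JITTER_M, size=(n_att, 2))
    xs = grid.x0 + (gj + 0.5) * grid.cellsize + jit[:, 0]
    ys = grid.y0 + (gi + 0.5) * grid.cellsize + jit[:, 1]
    in_wbp_cell = grid.wbp[gi, gj]
    p_success = config.fix_success_base * (1 - config.fix_success_wbp_penalty * in_wbp_cell)
    success = rng.random(n_att) < p_success

    wbp_geom = landscape.wbp_geometry
    true_wbp = (classify_points(wbp_geom, xs, ys) if not wbp_geom.is_empty
                else np.zeros(n_att, dtype=bool))
    true_sec = classify_points(landscape.secure_layer, xs, ys)

    dt0 = datetime(start_day.year, start_day.month, start_day.day)
    fix_interval = timedelta(days=1) / fpd
    attempts = []
    for k in range(n_att):
        day, slot = divmod(k, fpd)
        ts = dt0 + timedelta(days=day) + slot * fix_interval
        ok = bool(success[k])
        attempts.append(FixAttempt(
            bear_id=config.bear_id, timestamp=ts, success=ok,
            x=float(xs[k]) if ok else None, y=float(ys[k]) if ok else None,
            true_x=float(xs[k]), true_y=float(ys[k]),
            true_in_wbp=bool(true_wbp[k]), true_in_secure=bool(true_sec[k]),
        ))
    return BearSeason(
        bear_id=config.bear_id, sex=config.sex, year=config.year,
        attempts=attempts,
        local_availability_wbp=p_wbp, local_availability_secure=p_sec,
        true_use_wbp=float(in_wbp_cell.mean()),
        true_use_secure=float(grid.secure[gi, gj].mean()),
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

FIXES_PER_DAY_MIX = (7, 12, 24, 32, 48)


def mc_target_for_year(year, years, mc_start=0.69, mc_end=0.48):
    """Linearly interpolated target MC index across the study years."""
    y0, y1 = min(years), max(years)
    frac = 0.0 if y1 == y0 else (year - y0) / (y1 - y0)
    return mc_start + frac * (mc_end - mc_start)


def cohort_configs(years, bears_per_year, seed, cones_by_year=None,
                   mc_start=0.69, mc_end=0.48, cones_effect=0.0,
                   secure_strength=0.8, step_scale_km=0.25, range_radius_km=8.0,
                   fix_base_start=0.90, fix_base_gain=0.007, fix_wbp_penalty=0.08,
                   fixes_mix=FIXES_PER_DAY_MIX):
    """Build SimBearConfigs for a multi-year cohort with a programmed MC trend.

    The target MC declines linearly from ``mc_start`` to ``mc_end`` across the
    year span; ``cones_effect`` (log-odds per cone, males only) superimposes a
    response to annual cone production.  Fix success improves with year,
    emulating GPS hardware gains, while closed-canopy WBP retains a penalty.
    """
    years = sorted(years)
    cones_by_year = cones_by_year or {}
    mean_cones = (np.mean(list(cones_by_year.values())) if cones_by_year else 0.0)
    seeds = np.random.SeedSequence(int(seed)).generate_state(
        len(years) * bears_per_year * 4
    )
    configs = []
    k = 0
    for year in years:
        base = min(0.98, fix_base_start + fix_base_gain * (year - years[0]))
        for b in range(bears_per_year):
            sex = "F" if (k % 2 == 0) else "M"
            target = mc_target_for_year(year, years, mc_start, mc_end)
            s = strength_for_target_mc(min(max(target, 0.01), 0.99))
            if sex == "M" and cones_by_year:
                s += cones_effect * (cones_by_year[year] - mean_cones)
            configs.append(SimBearConfig(
                bear_id=f"bear_{year}_{b:02d}", sex=sex, year=year,
                wbp_selection_strength=s,
                secure_selection_strength=secure_strength,
                step_scale_km=step_scale_km,
                fixes_per_day=fixes_mix[k % len(fixes_mix)],
                fix_success_base=base,
                fix_success_wbp_penalty=fix_wbp_penalty,
                range_radius_km=range_radius_km,
                seed=int(seeds[k] % (2**31)),
            ))
            k += 1
    return configs


def simulate_cohort(landscape, configs, grid=None):
    """Simulate every configured bear on one landscape (shared raster grid)."""
    if grid is None:
        grid = build_grid(landscape)
    return [simulate_bear_track(landscape, c, grid=grid) for c in configs]
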