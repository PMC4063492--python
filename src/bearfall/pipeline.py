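"""End-to-end orchestration: simulate -> ranges -> use -> timing -> movement -> models.

Each stage reads the previous stage's persisted products from the output
directory and writes its own, so any stage can be re-run in isolation and a
full run is byte-reproducible from the master seed.  All outputs embed the
config hash and master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml

from . import habitat_use as hu
from . import homerange, io, models, movement, synthetic
from .layers import ImpactSurface, derive_secure, mean_impact

log = logging.getLogger("bearfall")

MIN_DAY_FRACTION = 0.95


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults emulate the 12-year study design."""

    extent_km: tuple = (30.0, 30.0)
    wbp_fraction: float = 0.25
    n_roads: int = 3
    years: tuple = tuple(range(2000, 2012))
    bears_per_year: int = 5
    mc_start: float = 0.69
    mc_end: float = 0.48
    cones_effect: float = 0.015
    secure_strength: float = 0.8
    step_scale_km: float = 0.25
    range_radius_km: float = 8.0
    fix_base_start: float = 0.90
    fix_base_gain: float = 0.007
    fix_wbp_penalty: float = 0.08
    severity_per_year: float = 0.01
    a_wbp_min: float = 0.05
    a_secure_max: float = 0.95
    day_use_threshold: float = 0.14
    max_gap_hours: float = 24.0
    log_floor_km: float = 0.001
    min_day_fraction: float = MIN_DAY_FRACTION
    fixes_mix: tuple = synthetic.FIXES_PER_DAY_MIX
    quantile_taus: tuple = (0.1, 0.5, 0.9)
    quantile_n_boot: int = 100
    seed: int = 1
    outdir: str = "bearfall_run"

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("extent_km", "years", "quantile_taus", "fixes_mix"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def config_hash(self):
        fields = {k: v for k, v in asdict(self).items() if k != "outdir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @property
    def out(self):
        p = Path(self.outdir)
        p.mkdir(parents=True, exist_ok=True)
        return p


def monitoring_filter(seasons, min_day_fraction=MIN_DAY_FRACTION):
    """Retain bear-seasons monitored on >= 95% of the 47 season days."""
    kept = [s for s in seasons if s.monitored_day_fraction >= min_day_fraction]
    log.info("monitoring filter: %d of %d seasons retained", len(kept), len(seasons))
    return kept


# ---------------------------------------------------------------------------
# Stage 1: simulate
# ---------------------------------------------------------------------------

def stage_simulate(cfg):
    out = cfg.out
    landscape = synthetic.generate_landscape(
        cfg.extent_km, cfg.wbp_fraction, cfg.n_roads, cfg.seed
    )
    io.write_geojson(landscape.wbp_polygons, out / "wbp.geojson")
    io.write_geojson(landscape.roads, out / "roads.geojson")
    io.write_geojson(landscape.park_polygons, out / "parks.geojson")

    cones = synthetic.simulate_cone_series(cfg.years, cfg.seed)
    pd.DataFrame([asdict(c) for c in cones]).to_csv(out / "cones.csv", index=False)

    for year in cfg.years:
        surf = synthetic.generate_impact_surface(
            landscape, year, min(cfg.years), cfg.severity_per_year, cfg.seed
        )
        io.write_ascii_grid(surf.delta, surf.x0, surf.y0, surf.cellsize,
                            out / f"impact_{year}.asc")
        flags = np.zeros(surf.delta.shape)
        flags[surf.wbp] = 1
        flags[surf.wbp & surf.canopy_ge_50] = 2
        io.write_ascii_grid(flags, surf.x0, surf.y0, surf.cellsize,
                            out / f"impact_flags_{year}.asc")

    cones_by_year = {c.year: c.median_cones for c in cones}
    configs = synthetic.cohort_configs(
        cfg.years, cfg.bears_per_year, cfg.seed, cones_by_year=cones_by_year,
        mc_start=cfg.mc_start, mc_end=cfg.mc_end, cones_effect=cfg.cones_effect,
        secure_strength=cfg.secure_strength, step_scale_km=cfg.step_scale_km,
        range_radius_km=cfg.range_radius_km, fix_base_start=cfg.fix_base_start,
        fix_base_gain=cfg.fix_base_gain, fix_wbp_penalty=cfg.fix_wbp_penalty,
        fixes_mix=tuple(cfg.fixes_mix),
    )
    seasons = synthetic.simulate_cohort(landscape, configs)
    io.write_fixes_csv(seasons, out / "fixes.csv", include_truth=True)
    log.info("simulate: %d bears, %d fix attempts", len(seasons),
             sum(len(s.attempts) for s in seasons))
    return landscape, cones, seasons


def _load_landscape(cfg):
    out = cfg.out
    wbp, _ = io.read_geojson(out / "wbp.geojson")
    roads, _ = io.read_geojson(out / "roads.geojson")
    parks, _ = io.read_geojson(out / "parks.geojson")
    W, H = cfg.extent_km[0] * 1000.0, cfg.extent_km[1] * 1000.0
    return synthetic.Landscape(
        wbp_polygons=wbp, roads=roads, park_polygons=parks,
        extent=shapely.geometry.box(0.0, 0.0, W, H),
    )


def _load_surface(cfg, year):
    out = cfg.out
    delta, x0, y0, cs = io.read_ascii_grid(out / f"impact_{year}.asc")
    flags, *_ = io.read_ascii_grid(out / f"impact_flags_{year}.asc")
    wbp = flags >= 1
    canopy = flags >= 2
    return ImpactSurface(x0=x0, y0=y0, cellsize=cs, delta=delta,
                         wbp=wbp, canopy_ge_50=canopy)


def _prepared_seasons(cfg, landscape):
    """Fixes CSV -> monitored seasons with imputed/weighted attempts."""
    seasons = io.read_fixes_csv(cfg.out / "fixes.csv")
    seasons = monitoring_filter(seasons, cfg.min_day_fraction)
    wbp_geom = landscape.wbp_geometry
    secure = derive_secure(landscape.roads, landscape.extent)
    max_gap = timedelta(hours=cfg.max_gap_hours)
    return [hu.assign_failed_fixes(s, wbp_geom, secure, max_gap) for s in seasons], \
        wbp_geom, secure


# ---------------------------------------------------------------------------
# Stage 2: home ranges
# ---------------------------------------------------------------------------

def stage_ranges(cfg):
    landscape = _load_landscape(cfg)
    seasons, wbp_geom, secure = _prepared_seasons(cfg, landscape)
    parks = shapely.union_all(landscape.park_polygons)
    surfaces = {}
    rows, geoms, props = [], [], []
    for s in seasons:
        pts = np.array([[a.x, a.y] for a in s.successful()])
        try:
            rng = homerange.fit_fall_range(pts, fallback_with_holes=True)
        except homerange.ALoCoHError as exc:
            log.warning("ranges: bear %s skipped (%s)", s.bear_id, exc)
            continue
        a_wbp = homerange.availability(rng, wbp_geom)
        a_sec = homerange.availability(rng, secure)
        if s.year not in surfaces:
            surfaces[s.year] = _load_surface(cfg, s.year)
        mdndvi = mean_impact(surfaces[s.year], rng.polygons)
        outside = not parks.covers(rng.polygons)
        rows.append({
            "bear_id": s.bear_id, "sex": s.sex, "year": s.year,
            "a_value": rng.a_value, "multiplier": rng.multiplier,
            "area_km2": rng.area_km2, "A_wbp": a_wbp, "A_secure": a_sec,
            "mean_delta_ndvi": "" if mdndvi is None else mdndvi,
            "resides_outside_parks": int(outside),
        })
        geoms.append(rng.polygons)
        props.append({"bear_id": s.bear_id, "a_value": rng.a_value,
                      "multiplier": rng.multiplier, "area_km2": rng.area_km2})
    pd.DataFrame(rows).to_csv(cfg.out / "ranges.csv", index=False)
    io.write_geojson(geoms, cfg.out / "ranges.geojson", properties=props)
    log.info("ranges: %d fall ranges built", len(rows))
    return rows


# ---------------------------------------------------------------------------
# Stage 3: use / selectivity
# ---------------------------------------------------------------------------

def _location_mean_impact(surface, season):
    """Mean delta-NDVI of scored cells at the bear's weighted locations."""
    vals, ws = [], []
    for a in season.attempts:
        if not a.weight or a.x is None:
            continue
        j = int((a.x - surface.x0) // surface.cellsize)
        i = int((a.y - surface.y0) // surface.cellsize)
        nr, nc = surface.delta.shape
        if 0 <= i < nr and 0 <= j < nc and np.isfinite(surface.delta[i, j]):
            vals.append(surface.delta[i, j])
            ws.append(a.weight)
    if not vals:
        return None
    return float(np.average(vals, weights=ws))


def stage_use(cfg):
    landscape = _load_landscape(cfg)
    seasons, _, _ = _prepared_seasons(cfg, landscape)
    ranges = pd.read_csv(cfg.out / "ranges.csv").set_index("bear_id")
    surfaces = {}
    rows = []
    for s in seasons:
        if s.bear_id not in ranges.index:
            continue
        r = ranges.loc[s.bear_id]
        if s.year not in surfaces:
            surfaces[s.year] = _load_surface(cfg, s.year)
        surf = surfaces[s.year]
        rec = hu.UseAvailability(
            bear_id=s.bear_id, sex=s.sex, year=s.year,
            U_wbp=hu.use_proportion(s, "wbp"),
            A_wbp=float(r["A_wbp"]),
            U_secure=hu.use_proportion(s, "secure"),
            A_secure=float(r["A_secure"]),
            mean_delta_ndvi_range=(None if pd.isna(r["mean_delta_ndvi"])
                                   else float(r["mean_delta_ndvi"])),
            mean_delta_ndvi_locations=_location_mean_impact(surf, s),
            resides_outside_parks=bool(r["resides_outside_parks"]),
            overall_weight=hu.overall_weight(s),
        )
        sel_w = hu.selectivity(rec, "wbp")
        sel_a = hu.selectivity(rec, "wbp_adjusted")
        sel_s = hu.selectivity(rec, "secure")
        days = hu.wbp_use_days(s, cfg.day_use_threshold)
        rows.append({
            "bear_id": s.bear_id, "sex": s.sex, "year": s.year,
            "A_wbp": rec.A_wbp, "U_wbp": rec.U_wbp,
            "A_secure": rec.A_secure, "U_secure": rec.U_secure,
            "MC_wbp": sel_w.value, "MC_wbp_eligible": int(sel_w.eligible),
            "MC_wbp_adj": sel_a.value,
            "MC_secure": sel_s.value, "MC_secure_eligible": int(sel_s.eligible),
            "exclusion_wbp": sel_w.exclusion_reason or "",
            "exclusion_secure": sel_s.exclusion_reason or "",
            "mean_delta_ndvi_range": rec.mean_delta_ndvi_range,
            "mean_delta_ndvi_locations": rec.mean_delta_ndvi_locations,
            "resides_outside_parks": int(rec.resides_outside_parks),
            "overall_weight": rec.overall_weight,
            "use_days_total": days.total_use_days,
            "use_days_mean_run": days.mean_run_length,
        })
    df = pd.DataFrame(rows)
    df.to_csv(cfg.out / "bears.csv", index=False)
    log.info("use: %d bears, %d eligible for WBP analysis",
             len(df), int(df["MC_wbp_eligible"].sum()) if len(df) else 0)
    return df


# ---------------------------------------------------------------------------
# Stage 4: timing (bear-day day-of-use table)
# ---------------------------------------------------------------------------

def stage_timing(cfg):
    landscape = _load_landscape(cfg)
    seasons, _, _ = _prepared_seasons(cfg, landscape)
    bears = pd.read_csv(cfg.out / "bears.csv").set_index("bear_id")
    cones = pd.read_csv(cfg.out / "cones.csv").set_index("year")
    rows = []
    for s in seasons:
        if s.bear_id not in bears.index or not bears.loc[s.bear_id, "MC_wbp_eligible"]:
            continue
        days = hu.wbp_use_days(s, cfg.day_use_threshold)
        for d in days.use_dates:
            rows.append({
                "bear_id": s.bear_id, "sex": s.sex, "year": s.year,
                "date": d.isoformat(), "doy": d.timetuple().tm_yday,
                "CONES": float(cones.loc[s.year, "median_cones"]),
            })
    df = pd.DataFrame(rows, columns=["bear_id", "sex", "year", "date", "doy",
                                     "CONES"])
    df.to_csv(cfg.out / "use_days.csv", index=False)
    log.info("timing: %d bear-days of WBP use", len(df))
    return df


# ---------------------------------------------------------------------------
# Stage 5: movement
# ---------------------------------------------------------------------------

def stage_movement(cfg):
    landscape = _load_landscape(cfg)
    seasons, _, _ = _prepared_seasons(cfg, landscape)
    tables = [movement.movement_table(s) for s in seasons if s.successful()]
    cols = ["bear_id", "date", "center_x", "center_y", "n_locations",
            "net_km", "radius_km"]
    df = (pd.concat(tables, ignore_index=True) if tables
          else pd.DataFrame(columns=cols))
    df.to_csv(cfg.out / "movement.csv", index=False)
    log.info("movement: %d bear-days", len(df))
    return df


# ---------------------------------------------------------------------------
# Stage 6: trend models
# ---------------------------------------------------------------------------

def _year_offset(cfg, years):
    return np.asarray(years) - min(cfg.years)


def _fit_candidate_set(fits_fn, specs):
    """Fit and rank a candidate set; None when any member cannot be fit
    (e.g., a design made rank-deficient by too few distinct years)."""
    fits = []
    for sp in specs:
        try:
            fits.append(fits_fn(sp))
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("models: %s / %s skipped (%s)", sp.response, sp.name, exc)
            return None
    return models.rank_models(fits)


def stage_models(cfg):
    out = cfg.out
    bears = pd.read_csv(out / "bears.csv")
    cones = pd.read_csv(out / "cones.csv").set_index("year")
    bears["CONES"] = cones.loc[bears["year"], "median_cones"].to_numpy()
    bears["SEX"] = bears["sex"]
    bears["YEAR"] = _year_offset(cfg, bears["year"])
    span = max(cfg.years) - min(cfg.years)
    mean_cones = float(bears["CONES"].mean())

    all_fits, contrasts = [], []

    def add_contrast(fit, label):
        setting_b = {"CONES": mean_cones, "C(SEX)[T.M]": 0.5, "YEAR": 0.0}
        setting_a = dict(setting_b, YEAR=float(span))
        c = models.predict_contrast(fit, setting_a, setting_b,
                                    description=f"{label}: year {max(cfg.years)}"
                                                f" vs {min(cfg.years)}")
        contrasts.append({
            "response": label, "model": fit.spec.name,
            "description": c.description, "estimate": c.estimate, "se": c.se,
            "ci_lower": c.ci_lower, "ci_upper": c.ci_upper,
        })

    # MC-index responses: weighted linear regression over bears
    for col, eligible_col, label in [
        ("MC_wbp", "MC_wbp_eligible", "MC index for WBP habitat"),
        ("MC_wbp_adj", "MC_wbp_eligible", "MC index for impact-adjusted WBP habitat"),
        ("MC_secure", "MC_secure_eligible", "MC index for secure habitat"),
    ]:
        data = bears[(bears[eligible_col] == 1) & bears[col].notna()].copy()
        data = data.rename(columns={col: "MC"})
        if len(data) < 10:
            log.warning("models: %s skipped (n=%d too small)", label, len(data))
            continue
        specs = models.candidate_specs("MC", "linear-weighted")
        fits = _fit_candidate_set(
            lambda sp: models.fit_linear_weighted(data, sp, weights="overall_weight"),
            specs,
        )
        if fits is None:
            continue
        for f in fits:
            f.spec.response = label
        all_fits += fits
        add_contrast(fits[0], label)

    # timing: quantile regressions on bear-day day-of-year
    use_days = pd.read_csv(out / "use_days.csv")
    if len(use_days) >= 30:
        use_days["SEX"] = use_days["sex"]
        use_days["YEAR"] = _year_offset(cfg, use_days["year"])
        for tau in cfg.quantile_taus:
            label = f"Day-of-year ({int(tau * 100)}th percentile)"
            specs = models.candidate_specs("doy", "quantile", tau=tau)
            fits = _fit_candidate_set(
                lambda sp: models.fit_quantile(use_days, sp,
                                               n_boot=cfg.quantile_n_boot,
                                               seed=cfg.seed),
                specs,
            )
            if fits is None:
                continue
            for f in fits:
                f.spec.response = label
            all_fits += fits
            add_contrast(fits[0], label)

    # movement: mixed-effects models on log distance / log radius
    mv = pd.read_csv(out / "movement.csv")
    if len(mv):
        mv = mv.merge(bears[["bear_id", "SEX", "YEAR", "CONES"]], on="bear_id")
        mv["bear_year"] = mv["bear_id"]
        for col, label in [("net_km", "Log (distance)"), ("radius_km", "Log (radius)")]:
            data = mv[mv[col].notna()].copy()
            if len(data) < 30:
                continue
            data["resp"] = np.log(np.maximum(data[col], cfg.log_floor_km))
            specs = models.candidate_specs("resp", "mixed-linear")
            fits = _fit_candidate_set(
                lambda sp: models.fit_mixed(data, sp, groups="bear_year"), specs,
            )
            if fits is None:
                continue
            for f in fits:
                f.spec.response = label
            all_fits += fits

    cols = ["response", "family", "model", "K", "n", "logLik", "AICc",
            "dAICc", "weight"]
    table = (models.model_table(all_fits) if all_fits
             else pd.DataFrame(columns=cols))
    table.to_csv(out / "model_table.csv", index=False)
    pd.DataFrame(contrasts, columns=["response", "model", "description",
                                     "estimate", "se", "ci_lower", "ci_upper"]
                 ).to_csv(out / "contrasts.csv", index=False)
    log.info("models: %d fits across %d candidate sets",
             len(all_fits), table["response"].nunique() if len(table) else 0)
    return table, contrasts


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(cfg):
    """Run every stage and write a machine-readable summary.

    Returns the summary dict (also persisted as summary.json).
    """
    out = cfg.out
    logging.basicConfig(level=logging.INFO, format="%(name)s %(message)s")
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    try:
        stage_simulate(cfg)
        stage_ranges(cfg)
        bears = stage_use(cfg)
        stage_timing(cfg)
        stage_movement(cfg)
        table, contrasts = stage_models(cfg)
    finally:
        log.removeHandler(fh)
        fh.close()

    top = (
        table.sort_values(["response", "AICc"]).groupby("response").first()
        if len(table) else pd.DataFrame()
    )
    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_bears": int(len(bears)),
        "n_eligible_wbp": int(bears["MC_wbp_eligible"].sum()) if len(bears) else 0,
        "n_eligible_secure": int(bears["MC_secure_eligible"].sum()) if len(bears) else 0,
        "top_models": {resp: row["model"] for resp, row in top.iterrows()},
        "contrasts": contrasts,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
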