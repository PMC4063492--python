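"""Daily movement indices: median centers, net displacement, activity radius.

Daily location centers (component-wise median x and y of the day's successful
fixes) equalize the number of observations per bear across fix schedules.
Net displacement is the distance between consecutive days' centers; the
activity radius is each day's distance from the fall-range center, itself the
coordinate-wise median of all successful fixes of the season.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LOG_FLOOR_KM = 0.001  # floor for zero distances before log transformation


def daily_centers(season):
    """One row per day with >= 1 successful fix: median x, median y, n."""
    rows = [
        (a.timestamp.date(), a.x, a.y) for a in season.attempts if a.success
    ]
    if not rows:
        raise ValueError("season has no successful fixes")
    df = pd.DataFrame(rows, columns=["date", "x", "y"])
    out = df.groupby("date", sort=True).agg(
        center_x=("x", "median"), center_y=("y", "median"), n_locations=("x", "size")
    ).reset_index()
    out.insert(0, "bear_id", season.bear_id)
    return out


def fall_center(season):
    """Coordinate-wise median over ALL successful fixes of the season."""
    xs = [a.x for a in season.attempts if a.success]
    ys = [a.y for a in season.attempts if a.success]
    if not xs:
        raise ValueError("season has no successful fixes")
    return float(np.median(xs)), float(np.median(ys))


def net_displacements(centers):
    """Net distance (km) between consecutive calendar days' centers.

    Rows are emitted only for days whose previous calendar day also has a
    center: a gap day yields no record spanning it.
    """
    df = centers.sort_values("date").reset_index(drop=True)
    dates = pd.to_datetime(df["date"])
    prev_ok = (dates - dates.shift(1)).dt.days == 1
    dx = df["center_x"].diff()
    dy = df["center_y"].diff()
    dist_km = np.hypot(dx, dy) / 1000.0
    out = df.loc[prev_ok, ["bear_id", "date"]].copy()
    out["net_km"] = dist_km[prev_ok].to_numpy()
    return out.reset_index(drop=True)


def activity_radii(centers, center):
    """Distance (km) from the fall-range center to each daily center."""
    cx, cy = center
    out = centers[["bear_id", "date"]].copy()
    out["radius_km"] = np.hypot(centers["center_x"] - cx,
                                centers["center_y"] - cy) / 1000.0
    return out.reset_index(drop=True)


def movement_table(season):
    """Per-day movement record for one bear: centers, net_km, radius_km."""
    centers = daily_centers(season)
    disp = net_displacements(centers)
    radii = activity_radii(centers, fall_center(season))
    out = centers.merge(disp, on=["bear_id", "date"], how="left")
    out = out.merge(radii, on=["bear_id", "date"], how="left")
    return out
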