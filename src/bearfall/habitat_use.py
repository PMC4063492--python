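"""Weighted habitat use, Manly-Chesson selectivity, and day-of-use timing.

GPS fix success is habitat-dependent (dense conifer canopy attenuates the
signal), so discarding failed fixes biases use estimates against closed-canopy
habitat.  Here every scheduled fix attempt is kept: failures bracketed by
successes get a time-interpolated coordinate, habitat flags at that
coordinate, and a certainty weight (concordance of the bracketing fixes'
habitat x a linear time decay).  Use proportions, selectivity indices and
day-of-use flags are all computed from these weighted attempts.

The Manly-Chesson (MC) standardized index for a two-habitat system is

    MC = (U/A) / (U/A + (1-U)/(1-A))

with U the (weighted) proportion of locations in the habitat and A the
proportion of the fall range covered by it; 0.5 means use proportional to
availability, values above 0.5 mean selection for the habitat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta

import numpy as np
from scipy import stats

from .layers import classify_point

SEASON_START = (8, 15)   # 15 Aug
SEASON_END = (9, 30)     # 30 Sep
SEASON_DAYS = 47
DAY_USE_THRESHOLD = 0.14
MAX_GAP_DEFAULT = timedelta(hours=24)
DISCORDANCE_FACTOR = 0.5
A_WBP_MIN = 0.05
A_SECURE_MAX = 0.95


def season_window(year):
    """The fall season: 15 Aug - 30 Sep inclusive (47 civil days)."""
    return date(year, *SEASON_START), date(year, *SEASON_END)


@dataclass
class FixAttempt:
    """One scheduled GPS acquisition.

    Successful attempts carry observed coordinates and weight 1.  Failed
    attempts may receive imputed coordinates, habitat flags, and a certainty
    weight in [0, 1]; weight 0 means the attempt is excluded from use sums.
    ``true_*`` fields hold simulator ground truth and are absent for real data.
    """

    bear_id: str
    timestamp: datetime
    success: bool
    x: float | None = None
    y: float | None = None
    in_wbp: bool | None = None
    in_secure: bool | None = None
    weight: float | None = None
    true_x: float | None = None
    true_y: float | None = None
    true_in_wbp: bool | None = None
    true_in_secure: bool | None = None

    def __post_init__(self):
        if self.success:
            if self.x is None or self.y is None:
                raise ValueError("successful fix without coordinates")
            if self.weight is None:
                self.weight = 1.0
        elif self.weight is None:
            self.weight = 0.0


@dataclass
class BearSeason:
    """All fix attempts of one bear in one fall season."""

    bear_id: str
    sex: str
    year: int
    attempts: list = field(default_factory=list)
    # simulator ground truth, raster resolution (absent for real data):
    local_availability_wbp: float | None = None
    local_availability_secure: float | None = None
    true_use_wbp: float | None = None
    true_use_secure: float | None = None

    def successful(self):
        return [a for a in self.attempts if a.success]

    @property
    def monitored_day_fraction(self):
        """Fraction of the 47 season days with >= 1 successful fix."""
        days = {a.timestamp.date() for a in self.attempts if a.success}
        return len(days) / SEASON_DAYS


@dataclass
class UseAvailability:
    bear_id: str
    sex: str
    year: int
    U_wbp: float | None = None
    A_wbp: float | None = None
    U_secure: float | None = None
    A_secure: float | None = None
    mean_delta_ndvi_range: float | None = None
    mean_delta_ndvi_locations: float | None = None
    resides_outside_parks: bool = True
    overall_weight: float = 1.0


@dataclass
class SelectivityIndex:
    habitat_label: str
    value: float | None
    eligible: bool
    exclusion_reason: str | None = None


def assign_failed_fixes(season, wbp_layer, secure_layer, max_gap=MAX_GAP_DEFAULT):
    """Impute failed fixes and assign habitat flags to every attempt.

    A failed attempt bracketed by successful fixes whose separation is at most
    ``max_gap`` receives a coordinate by linear interpolation in time and a
    weight = concordance x decay, where concordance is 1 when both bracketing
    fixes share the imputed point's habitat class on every layer (0.5
    otherwise) and decay = max(0, 1 - gap / max_gap).  Unbracketed failures
    keep weight 0 and unknown flags.  Returns a new BearSeason.
    """
    from .layers import classify_points

    attempts = season.attempts
    times = [a.timestamp for a in attempts]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("attempts must be time-ordered")

    n = len(attempts)
    success = np.array([a.success for a in attempts])
    succ_idx = np.flatnonzero(success)
    out = [replace(a) for a in attempts]

    # bracket each failure with the nearest successful fixes in time
    pos = np.searchsorted(succ_idx, np.arange(n))
    prev_i = np.where(pos > 0, succ_idx[np.clip(pos - 1, 0, None)], -1)
    next_i = np.where(pos < len(succ_idx), succ_idx[np.clip(pos, None, len(succ_idx) - 1)], -1)

    imput, gaps, fracs = [], [], []
    for i in np.flatnonzero(~success):
        p, q = prev_i[i], next_i[i]
        a = out[i]
        a.weight = 0.0
        a.in_wbp = a.in_secure = None
        if p < 0 or q < 0:
            continue
        gap = times[q] - times[p]
        if gap > max_gap:
            continue
        frac = (times[i] - times[p]) / gap if gap else 0.5
        pa, na = attempts[p], attempts[q]
        a.x = pa.x + frac * (na.x - pa.x)
        a.y = pa.y + frac * (na.y - pa.y)
        imput.append((i, p, q))
        gaps.append(gap)

    # one vectorized point-in-polygon pass over every located attempt
    located = [i for i in range(n) if out[i].x is not None]
    xs = np.array([out[i].x for i in located])
    ys = np.array([out[i].y for i in located])
    wbp_flags = dict(zip(located, classify_points(wbp_layer, xs, ys)))
    sec_flags = dict(zip(located, classify_points(secure_layer, xs, ys)))

    for i in located:
        if out[i].success:
            out[i].in_wbp = bool(wbp_flags[i])
            out[i].in_secure = bool(sec_flags[i])
            out[i].weight = 1.0
    for (i, p, q), gap in zip(imput, gaps):
        a = out[i]
        a.in_wbp = bool(wbp_flags[i])
        a.in_secure = bool(sec_flags[i])
        concordant = (
            wbp_flags[p] == wbp_flags[q] == wbp_flags[i]
            and sec_flags[p] == sec_flags[q] == sec_flags[i]
        )
        concordance = 1.0 if concordant else DISCORDANCE_FACTOR
        decay = max(0.0, 1.0 - gap / max_gap)
        a.weight = concordance * decay
    return replace(season, attempts=out)


def overall_weight(season):
    """Sum of attempt weights / number of attempts (the per-bear weight)."""
    if not season.attempts:
        raise ValueError("season has no attempts")
    return float(np.mean([a.weight for a in season.attempts]))


def use_proportion(season, habitat):
    """Certainty-weighted proportion of locations in a habitat.

    ``habitat`` is "wbp" or "secure".  U = sum(w * 1[in habitat]) / sum(w)
    over attempts with positive weight.
    """
    attr = {"wbp": "in_wbp", "secure": "in_secure"}[habitat]
    w = np.array([a.weight for a in season.attempts])
    flags = np.array([bool(getattr(a, attr)) if getattr(a, attr) is not None else False
                      for a in season.attempts])
    mask = w > 0
    if not mask.any():
        raise ValueError("all attempt weights are zero")
    return float((w[mask] * flags[mask]).sum() / w[mask].sum())


def mc_index(U, A):
    """Manly-Chesson standardized selectivity for a two-habitat system.

    Returns None when A is 0 or 1 (the index is not calculable: zero
    availability of one habitat puts a zero in the denominator).
    """
    if not 0 <= U <= 1:
        raise ValueError("U outside [0, 1]")
    if not 0 <= A <= 1:
        raise ValueError("A outside [0, 1]")
    if A in (0.0, 1.0):
        return None
    r_use = U / A
    r_non = (1 - U) / (1 - A)
    return float(r_use / (r_use + r_non))


def impact_adjusted_mc(U, A, mean_delta_ndvi):
    """MC index against availability discounted for canopy decline.

    A' = A x (1 - mean delta-NDVI); the adjusted index is >= the raw index
    whenever any use occurred and the impact is positive.
    """
    if not 0 <= mean_delta_ndvi < 1:
        raise ValueError("mean_delta_ndvi outside [0, 1)")
    a_adj = A * (1 - mean_delta_ndvi)
    if a_adj == 0:
        return None
    return mc_index(U, a_adj)


def eligibility(record, resides_outside_parks, analysis):
    """Sample-inclusion rule for the selection analyses.

    WBP (raw or impact-adjusted): exclude bears whose range has < 5% WBP.
    Secure: exclude bears with > 95% secure habitat or residing entirely
    within national parks.  Boundary values (exactly 0.05 / 0.95) are eligible.
    """
    if analysis in ("wbp", "wbp_adjusted"):
        if record.A_wbp is None or record.A_wbp < A_WBP_MIN:
            return False, f"A_WBP < {A_WBP_MIN}"
        return True, None
    if analysis == "secure":
        if record.A_secure is None or record.A_secure > A_SECURE_MAX:
            return False, f"A_secure > {A_SECURE_MAX}"
        if not resides_outside_parks:
            return False, "range entirely within national parks"
        return True, None
    raise ValueError(f"unknown analysis {analysis!r}")


def selectivity(record, analysis, resides_outside_parks=None):
    """UseAvailability -> SelectivityIndex for one analysis label."""
    outside = (record.resides_outside_parks if resides_outside_parks is None
               else resides_outside_parks)
    ok, reason = eligibility(record, outside, analysis)
    if not ok:
        return SelectivityIndex(analysis, None, False, reason)
    if analysis == "wbp":
        val = mc_index(record.U_wbp, record.A_wbp)
    elif analysis == "wbp_adjusted":
        impact = record.mean_delta_ndvi_range or 0.0
        val = impact_adjusted_mc(record.U_wbp, record.A_wbp, impact)
    else:
        val = mc_index(record.U_secure, record.A_secure)
    if val is None:
        return SelectivityIndex(analysis, None, False, "zero availability")
    return SelectivityIndex(analysis, val, True)


@dataclass
class DayUseSummary:
    flags: dict                 # date -> bool (defined days only)
    total_use_days: int
    mean_run_length: float | None
    use_dates: list


def wbp_use_days(season, threshold=DAY_USE_THRESHOLD):
    """Flag each season day as a WBP-use day.

    A day is a use day when the weighted proportion of its positive-weight
    attempts inside WBP is at least ``threshold`` (default 14%, the minimum
    detectable daily use for a 7-fix/day schedule: 1 of 7).  Days without
    positive-weight attempts are undefined and excluded; an undefined day
    breaks a consecutive run.
    """
    start, end = season_window(season.year)
    by_day = {}
    for a in season.attempts:
        if a.weight and a.weight > 0 and a.in_wbp is not None:
            by_day.setdefault(a.timestamp.date(), []).append(a)
    flags = {}
    d = start
    while d <= end:
        if d in by_day:
            w = np.array([a.weight for a in by_day[d]])
            ind = np.array([bool(a.in_wbp) for a in by_day[d]])
            flags[d] = bool((w * ind).sum() / w.sum() >= threshold)
        d += timedelta(days=1)

    use_dates = sorted(dd for dd, f in flags.items() if f)
    runs = []
    d = start
    current = 0
    while d <= end:
        if flags.get(d, False):
            current += 1
        elif current:
            runs.append(current)
            current = 0
        d += timedelta(days=1)
    if current:
        runs.append(current)
    mean_run = float(np.mean(runs)) if runs else None
    return DayUseSummary(flags=flags, total_use_days=len(use_dates),
                         mean_run_length=mean_run, use_dates=use_dates)


@dataclass
class PairedTestResult:
    mean_difference: float
    se: float
    t: float | None
    df: int
    p: float | None
    degenerate: bool = False


def compare_impact_use_vs_availability(cohort):
    """Paired t-test of mean delta-NDVI at locations vs within the range."""
    pairs = [
        (r.mean_delta_ndvi_locations, r.mean_delta_ndvi_range)
        for r in cohort
        if r.mean_delta_ndvi_locations is not None and r.mean_delta_ndvi_range is not None
    ]
    if len(pairs) < 2:
        raise ValueError("need >= 2 paired records")
    diffs = np.array([u - a for u, a in pairs])
    n = len(diffs)
    mean = float(diffs.mean())
    se = float(diffs.std(ddof=1) / np.sqrt(n))
    if se == 0:
        if mean == 0:
            return PairedTestResult(0.0, 0.0, None, n - 1, 1.0, degenerate=False)
        return PairedTestResult(mean, 0.0, None, n - 1, None, degenerate=True)
    t = mean / se
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(mean, se, float(t), n - 1, p)
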