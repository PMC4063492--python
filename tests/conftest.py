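import numpy as np
import pytest

import bearfall as bf
from bearfall.synthetic import build_grid

# reference annual cone-count series (median cones/tree on production
# transects, 2000-2011) used as the CONES covariate throughout
CONE_SERIES = {
    2000: 0, 2001: 13, 2002: 0, 2003: 16, 2004: 1, 2005: 8,
    2006: 22, 2007: 8, 2008: 1, 2009: 20, 2010: 2, 2011: 12.5,
}


@pytest.fixture(scope="session")
def landscape():
    return bf.generate_landscape((20, 20), 0.3, 2, seed=7)


@pytest.fixture(scope="session")
def grid(landscape):
    return build_grid(landscape)


@pytest.fixture(scope="session")
def cone_series():
    return dict(CONE_SERIES)


def make_season(coords_by_day, year=2005, bear_id="b1", sex="F",
                success=None, fixes_per_day=None):
    """Build a BearSeason from {day_index: [(x, y), ...]} starting 15 Aug."""
    from datetime import datetime, timedelta

    from bearfall.habitat_use import BearSeason, FixAttempt

    t0 = datetime(year, 8, 15)
    attempts = []
    for day, pts in sorted(coords_by_day.items()):
        n = len(pts)
        for k, (x, y) in enumerate(pts):
            ts = t0 + timedelta(days=day) + timedelta(days=1) * k / max(n, 1)
            ok = True if success is None else success[(day, k)]
            attempts.append(FixAttempt(
                bear_id=bear_id, timestamp=ts, success=ok,
                x=x if ok else None, y=y if ok else None,
                true_x=x, true_y=y,
            ))
    return BearSeason(bear_id=bear_id, sex=sex, year=year, attempts=attempts)
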