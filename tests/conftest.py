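import datetime as dt

import numpy as np
import pytest

from chillday import DailyTemperatureRecord, DormancySeason


def make_records(start, temps):
    """Consecutive daily records from `start`; temps = [(tmax, tmin), ...]."""
    return [
        DailyTemperatureRecord(start + dt.timedelta(days=i), tx, tn)
        for i, (tx, tn) in enumerate(temps)
    ]


def constant_season(start_year=2009, cold_days=20, cold=(4.0, 2.0), warm=(14.0, 6.0)):
    """A 273-day season: `cold_days` of `cold` then warm days to June 30."""
    onset = dt.date(start_year, 10, 1)
    n = (dt.date(start_year + 1, 6, 30) - onset).days + 1
    temps = [cold if i < cold_days else warm for i in range(n)]
    return DormancySeason(
        f"{start_year}–{start_year + 1}", onset, make_records(onset, temps)
    )


@pytest.fixture
def step_season():
    """Cold step then warm step; hand-traceable accumulation."""
    return constant_season()


def triangle_day_mean_excess(tmax, tmin, threshold, n=20001):
    """Numerically integrated degree-days above `threshold` for a triangular
    diurnal course between tmin and tmax (independent oracle)."""
    u = np.linspace(0.0, 1.0, n)
    temp = np.where(
        u <= 0.5,
        tmin + (tmax - tmin) * 2.0 * u,
        tmax - (tmax - tmin) * 2.0 * (u - 0.5),
    )
    return float(np.trapezoid(np.maximum(temp - threshold, 0.0), u))


def oracle_chill_antichill(tmax, tmin, tc, n=20001):
    """Triangle-area oracle for the daily (Cd, Ca) contributions.

    Anti-chill is the triangle area above tc; chill is minus the area
    between the chilling floor max(tmin, 0) and tc.
    """
    if tmax == tmin:
        ta = tmax
        return 0.0, max(0.0, ta - tc)
    ca = triangle_day_mean_excess(tmax, tmin, tc, n=n)
    floor = max(tmin, 0.0)
    above_floor = triangle_day_mean_excess(tmax, tmin, floor, n=n)
    above_upper = triangle_day_mean_excess(tmax, tmin, max(tc, floor), n=n)
    return -(above_floor - above_upper), ca
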