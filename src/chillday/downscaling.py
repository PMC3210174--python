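"""Temporal downscaling of monthly climate normals to daily series.

Thirty-year monthly normals (12 Tmax + 12 Tmin values) are interpolated to
a 365-day daily climatology by exact trigonometric interpolation: the
12-dimensional space spanned by a mean term, harmonics k = 1..5 (sine and
cosine) and the Nyquist cosine (k = 6) on a 365-day period is fitted to
pass exactly through the 12 monthly values anchored at mid-month days of
year.  Tmax and Tmin are interpolated independently; the few days where the
curves cross are clamped to their midpoint and counted.

The resulting climatology is a repeating "normal year" (no leap day): it is
wrapped into a synthetic dormancy season (Oct 1 → Jun 30) so the phenology
engine can run directly on a climate-normal period.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .weather_io import DailyTemperatureRecord, DormancySeason, season_label

__all__ = [
    "MID_MONTH_DOY",
    "MonthlyNormals",
    "DailyClimatology",
    "trig_interpolate_monthly",
    "downscale_normals",
    "climatology_to_season",
    "read_normals_csv",
]

#: mid-month anchor days of year (non-leap calendar), Jan..Dec
MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])

#: nominal (non-leap) season start year used when a climatology is wrapped
#: into a dormancy season; 2001/2002 are both non-leap years
NOMINAL_START_YEAR = 2001


@dataclass(frozen=True)
class MonthlyNormals:
    """12-month Tmax/Tmin climatology for one location and normal period."""

    location: str
    period: str  # e.g. "2020s" = 2010–2039
    tmax: tuple[float, ...]
    tmin: tuple[float, ...]
    scenario: str = ""

    def __post_init__(self) -> None:
        if len(self.tmax) != 12 or len(self.tmin) != 12:
            raise ValueError("normals require exactly 12 monthly values each")
        if not all(np.isfinite(self.tmax)) or not all(np.isfinite(self.tmin)):
            raise ValueError("non-finite value in monthly normals")
        for m, (hi, lo) in enumerate(zip(self.tmax, self.tmin), start=1):
            if hi < lo:
                raise ValueError(f"month {m}: tmax {hi} < tmin {lo}")


@dataclass
class DailyClimatology:
    """365-day (tmax, tmin) normal year indexed by 1-based DOY."""

    tmax: np.ndarray = field(repr=False)
    tmin: np.ndarray = field(repr=False)
    clamped_days: int = 0

    def __post_init__(self) -> None:
        if self.tmax.shape != (365,) or self.tmin.shape != (365,):
            raise ValueError("climatology arrays must have shape (365,)")


def _design_matrix(doy: np.ndarray) -> np.ndarray:
    theta = 2.0 * np.pi * doy[:, None] / 365.0
    k = np.arange(1, 6)
    cols = [np.ones((doy.size, 1)), np.cos(theta * k), np.sin(theta * k),
            np.cos(theta * 6)]
    return np.hstack(cols)


def trig_interpolate_monthly(values: Sequence[float]) -> np.ndarray:
    """Exact trigonometric interpolation of 12 monthly values to 365 days.

    Solves the 12×12 linear system anchoring the curve at the mid-month
    days of year, then evaluates at DOY 1..365.  The curve passes through
    every anchor (to solver precision) and reproduces any function already
    in the harmonic space — in particular constants and single harmonics.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (12,):
        raise ValueError(f"expected 12 monthly values, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite monthly value")
    coeffs = np.linalg.solve(_design_matrix(MID_MONTH_DOY.astype(float)), v)
    days = np.arange(1, 366, dtype=float)
    return _design_matrix(days) @ coeffs


def downscale_normals(normals: MonthlyNormals) -> DailyClimatology:
    """Interpolate Tmax and Tmin normals independently to a daily year.

    Days where the interpolated tmax dips below tmin (possible because the
    two curves are fitted separately) have both set to their midpoint; the
    number of such days is recorded in ``clamped_days``.
    """
    tmax = trig_interpolate_monthly(normals.tmax)
    tmin = trig_interpolate_monthly(normals.tmin)
    crossing = tmax < tmin
    n_cross = int(np.count_nonzero(crossing))
    if n_cross:
        mid = (tmax[crossing] + tmin[crossing]) / 2.0
        tmax[crossing] = mid
        tmin[crossing] = mid
    return DailyClimatology(tmax=tmax, tmin=tmin, clamped_days=n_cross)


def climatology_to_season(
    clim: DailyClimatology, start_year: int = NOMINAL_START_YEAR
) -> DormancySeason:
    """Wrap a normal year into an Oct 1 → Jun 30 dormancy season.

    DOY 274 (Oct 1) through 365 of the nominal start year is followed by
    DOY 1 through 181 (Jun 30) of the same repeating year.  The nominal
    year pair must both be non-leap so calendar dates align with the
    365-day climatology.
    """
    onset = _dt.date(start_year, 10, 1)
    end = _dt.date(start_year + 1, 6, 30)
    n_days = (end - onset).days + 1
    if n_days != 273:
        raise ValueError(f"start year {start_year} spans a leap day; choose a non-leap pair")
    records = []
    for i in range(n_days):
        date = onset + _dt.timedelta(days=i)
        doy0 = (274 + i - 1) % 365  # 0-based index into the repeating year
        records.append(
            DailyTemperatureRecord(date, float(clim.tmax[doy0]), float(clim.tmin[doy0]))
        )
    return DormancySeason(season_label(start_year), onset, records)


def read_normals_csv(path: str | Path) -> list[MonthlyNormals]:
    """Read long-format normals: location_id, period, month (1–12), tmax, tmin.

    An optional ``scenario`` column is carried through.  Each
    (location, scenario, period) group must contain all 12 months.
    """
    df = pd.read_csv(path)
    required = {"location_id", "period", "month", "tmax", "tmin"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"missing column(s) {sorted(missing)} in {path}")
    if "scenario" not in df.columns:
        df = df.assign(scenario="")
    out = []
    for (loc, scen, period), grp in df.groupby(
        ["location_id", "scenario", "period"], sort=True
    ):
        grp = grp.sort_values("month")
        if list(grp["month"]) != list(range(1, 13)):
            raise ValueError(
                f"{loc}/{scen}/{period}: months must be exactly 1..12, got {list(grp['month'])}"
            )
        out.append(
            MonthlyNormals(
                location=str(loc),
                period=str(period),
                tmax=tuple(float(x) for x in grp["tmax"]),
                tmin=tuple(float(x) for x in grp["tmin"]),
                scenario=str(scen),
            )
        )
    return out
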