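"""Scenario projection tables: mean bloom dates, advancement, spread.

A calibrated cultivar model is applied to each (location, scenario, normal
period) monthly climatology — downscaled to a daily normal year and run
through the chill-day engine — giving one projected mean peak bloom date
per cell.  Summaries follow the conventions of climate-normal reporting:
all date arithmetic uses the non-leap day-of-year mapping, advancement is
the baseline DOY minus the projected DOY (positive = earlier bloom), and
spread across locations is the sample (n−1) standard deviation of DOYs,
reported to one decimal day.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chill_model import ModelParams, run_season
from .downscaling import MonthlyNormals, climatology_to_season, downscale_normals

__all__ = [
    "ProjectionCell",
    "BaselinePBD",
    "date_to_doy",
    "doy_to_date",
    "advancement",
    "mean_advancement",
    "sd_across",
    "project",
]

_NONLEAP_YEAR = 2001
_LEAP_YEAR = 2000

#: plausible spring-bloom DOY window (Feb 1 – Jun 30); cells outside are flagged
_PLAUSIBLE_DOY = (32, 181)


def date_to_doy(date: _dt.date, leap: bool = False) -> int:
    """1-based day of year of a (month, day) pair.

    With ``leap=False`` (the default, used for all normal-year arithmetic)
    the non-leap calendar applies, so March 1 is always DOY 60.
    """
    year = _LEAP_YEAR if leap else _NONLEAP_YEAR
    return _dt.date(year, date.month, date.day).timetuple().tm_yday


def doy_to_date(doy: int, leap: bool = False) -> _dt.date:
    year = _LEAP_YEAR if leap else _NONLEAP_YEAR
    return _dt.date(year, 1, 1) + _dt.timedelta(days=int(doy) - 1)


@dataclass(frozen=True)
class BaselinePBD:
    """Observed mean peak bloom date of a cultivar in the reference period."""

    cultivar: str
    mean_pbd: _dt.date

    @property
    def doy(self) -> int:
        return date_to_doy(self.mean_pbd)


@dataclass(frozen=True)
class ProjectionCell:
    """Projected mean PBD for one cultivar × location × scenario × period."""

    cultivar: str
    location: str
    scenario: str
    period: str
    pbd: _dt.date | None
    status: str = "bloomed"

    @property
    def doy(self) -> int | None:
        return None if self.pbd is None else date_to_doy(self.pbd)

    @property
    def anomalous(self) -> bool:
        if self.doy is None:
            return True
        return not (_PLAUSIBLE_DOY[0] <= self.doy <= _PLAUSIBLE_DOY[1])


def advancement(baseline: BaselinePBD, cell: ProjectionCell) -> int:
    """Days the projected bloom advances on the baseline (positive = earlier)."""
    if baseline.cultivar != cell.cultivar:
        raise ValueError(
            f"cultivar mismatch: baseline {baseline.cultivar!r} vs cell {cell.cultivar!r}"
        )
    if cell.doy is None:
        raise ValueError(f"cell {cell.location}/{cell.period} has no bloom date")
    return baseline.doy - cell.doy


def mean_advancement(
    cells: Sequence[ProjectionCell], baselines: Mapping[str, BaselinePBD]
) -> float:
    """Arithmetic mean of per-cultivar advancements for one location/period.

    Expects exactly one cell per cultivar; every cell's cultivar must have a
    baseline.
    """
    if not cells:
        raise ValueError("no cells")
    seen = [c.cultivar for c in cells]
    if len(set(seen)) != len(seen):
        raise ValueError(f"duplicate cultivar among cells: {seen}")
    missing = [c.cultivar for c in cells if c.cultivar not in baselines]
    if missing:
        raise ValueError(f"missing baseline for cultivar(s): {missing}")
    return float(np.mean([advancement(baselines[c.cultivar], c) for c in cells]))


def sd_across(dates: Sequence[_dt.date]) -> float:
    """Sample (n−1) standard deviation of non-leap DOYs, one-decimal days."""
    if len(dates) < 2:
        raise ValueError("need at least 2 dates")
    doys = np.array([date_to_doy(d) for d in dates], dtype=float)
    return round(float(np.std(doys, ddof=1)), 1)


def project(
    params: Mapping[str, ModelParams] | ModelParams,
    normals: Sequence[MonthlyNormals],
    baselines: Mapping[str, BaselinePBD] | None = None,
    cultivar: str = "cultivar",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run calibrated model(s) over a set of per-location/period normals.

    Returns a tidy cell table (cultivar, location, scenario, period,
    pbd_date, pbd_doy, status, advancement_days) and a summary table with
    the cross-location SD per cultivar × scenario × period.  Cells where
    the model fails to release or bloom are flagged by status, never
    dropped silently.
    """
    if not normals:
        raise ValueError("empty normals set")
    by_cultivar: Mapping[str, ModelParams]
    if isinstance(params, ModelParams):
        by_cultivar = {cultivar: params}
    else:
        by_cultivar = params
    baselines = baselines or {}

    rows = []
    for cv, p in by_cultivar.items():
        for nm in normals:
            season = climatology_to_season(downscale_normals(nm))
            pred = run_season(season, p)
            cell = ProjectionCell(
                cultivar=cv,
                location=nm.location,
                scenario=nm.scenario,
                period=nm.period,
                pbd=pred.pbd,
                status=pred.status,
            )
            adv = (
                advancement(baselines[cv], cell)
                if cv in baselines and cell.pbd is not None
                else None
            )
            rows.append(
                {
                    "cultivar": cv,
                    "location": nm.location,
                    "scenario": nm.scenario,
                    "period": nm.period,
                    "pbd_date": None if cell.pbd is None else cell.pbd.strftime("%m-%d"),
                    "pbd_doy": cell.doy,
                    "status": pred.status,
                    "anomalous": cell.anomalous,
                    "advancement_days": adv,
                }
            )
    cells = pd.DataFrame(rows)

    summary_rows = []
    for (cv, scen, period), grp in cells.groupby(["cultivar", "scenario", "period"]):
        ok = grp[grp["status"] == "bloomed"]
        doys = ok["pbd_doy"].to_numpy(dtype=float)
        summary_rows.append(
            {
                "cultivar": cv,
                "scenario": scen,
                "period": period,
                "n_locations": len(ok),
                "mean_pbd_doy": float(np.mean(doys)) if len(ok) else None,
                "sd_across_locations": (
                    round(float(np.std(doys, ddof=1)), 1) if len(ok) >= 2 else None
                ),
                "mean_advancement_days": (
                    float(np.mean(ok["advancement_days"].dropna()))
                    if ok["advancement_days"].notna().any()
                    else None
                ),
            }
        )
    return cells, pd.DataFrame(summary_rows)
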