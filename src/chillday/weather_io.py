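"""Reading, validation and season assembly for daily temperature data.

Daily weather arrives as station CSV exports (date, Tmax, Tmin in °C, header
names configurable to accommodate NOAA daily-summary layouts).  Observed
peak-bloom dates (PBD) arrive as (season start year, bloom date) CSVs.  The
model consumes *dormancy seasons*: consecutive daily records from October 1
of a start year through June 30 of the following year; short gaps are filled
by linear interpolation, long gaps reject the season.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailyTemperatureRecord",
    "DormancySeason",
    "ObservedPBD",
    "RejectedRow",
    "WeatherReadResult",
    "SeasonExtractionError",
    "read_daily_csv",
    "write_daily_csv",
    "extract_season",
    "read_observed_pbd",
    "season_label",
]

#: plausibility bounds for screened temperatures, °C
TEMP_MIN, TEMP_MAX = -60.0, 60.0

DEFAULT_COLUMNS: Mapping[str, str] = {"date": "date", "tmax": "tmax", "tmin": "tmin"}


@dataclass(frozen=True, order=True)
class DailyTemperatureRecord:
    """One day's maximum and minimum air temperature (°C)."""

    date: _dt.date
    tmax: float
    tmin: float

    @property
    def ta(self) -> float:
        """Daily mean temperature, always derived as (tmax + tmin) / 2."""
        return (self.tmax + self.tmin) / 2.0


class RejectedRow(NamedTuple):
    line: int  # 1-based line number in the source file (header = line 1)
    reason: str
    content: str


@dataclass
class WeatherReadResult:
    """Parsed records plus a report of rejected rows."""

    records: list[DailyTemperatureRecord]
    rejects: list[RejectedRow]


def season_label(start_year: int) -> str:
    return f"{start_year}–{start_year + 1}"


@dataclass
class DormancySeason:
    """Consecutive daily records from Oct 1 (onset) through June 30."""

    label: str
    onset: _dt.date
    records: list[DailyTemperatureRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("season has no records")
        if self.records[0].date != self.onset:
            raise ValueError(
                f"first record {self.records[0].date} != onset {self.onset}"
            )
        for prev, cur in zip(self.records, self.records[1:]):
            if (cur.date - prev.date).days != 1:
                raise ValueError(
                    f"records not consecutive at {prev.date} -> {cur.date}"
                )

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ObservedPBD:
    """An observed peak bloom date for the season starting `start_year`.

    Peak bloom is the day 70 % of blossoms on the monitored trees are open;
    it must fall between Jan 1 and Jun 30 of ``start_year + 1``.
    """

    start_year: int
    bloom_date: _dt.date

    def __post_init__(self) -> None:
        year = self.start_year + 1
        if not (_dt.date(year, 1, 1) <= self.bloom_date <= _dt.date(year, 6, 30)):
            raise ValueError(
                f"bloom date {self.bloom_date} outside Jan 1–Jun 30 {year} "
                f"for season starting {self.start_year}"
            )

    @property
    def doy(self) -> int:
        """1-based day of year of the bloom date within its calendar year."""
        return self.bloom_date.timetuple().tm_yday


class SeasonExtractionError(ValueError):
    """Season could not be assembled (gap too long or boundary missing)."""


def read_daily_csv(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> WeatherReadResult:
    """Read a daily temperature CSV into sorted records.

    ``columns`` maps the logical names ``date``/``tmax``/``tmin`` to the
    file's header names.  Rows with unparseable dates, non-numeric or
    implausible (outside ±60 °C) temperatures, or ``tmax < tmin`` are
    excluded and reported with their 1-based line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, dtype=str)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise KeyError(f"missing mapped column(s) {missing} in {path}")

    records: list[DailyTemperatureRecord] = []
    rejects: list[RejectedRow] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header occupies line 1
        raw = dict(zip(df.columns, row))
        content = ",".join("" if pd.isna(v) else str(v) for v in row)
        try:
            date = _dt.date.fromisoformat(str(raw[colmap["date"]]).strip())
        except (ValueError, TypeError):
            rejects.append(RejectedRow(line, "unparseable date", content))
            continue
        try:
            tmax = float(raw[colmap["tmax"]])
            tmin = float(raw[colmap["tmin"]])
        except (ValueError, TypeError):
            rejects.append(RejectedRow(line, "non-numeric temperature", content))
            continue
        if not (np.isfinite(tmax) and np.isfinite(tmin)):
            rejects.append(RejectedRow(line, "non-finite temperature", content))
            continue
        if tmax < tmin:
            rejects.append(RejectedRow(line, "tmax < tmin", content))
            continue
        if not (TEMP_MIN <= tmin <= TEMP_MAX and TEMP_MIN <= tmax <= TEMP_MAX):
            rejects.append(RejectedRow(line, "temperature outside ±60 °C", content))
            continue
        records.append(DailyTemperatureRecord(date, tmax, tmin))
    records.sort(key=lambda r: r.date)
    return WeatherReadResult(records, rejects)


def write_daily_csv(records: Iterable[DailyTemperatureRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "date": [r.date.isoformat() for r in records],
            "tmax": [r.tmax for r in records],
            "tmin": [r.tmin for r in records],
        }
    )
    df.to_csv(path, index=False)


def extract_season(
    records: Sequence[DailyTemperatureRecord], start_year: int, max_gap: int = 3
) -> DormancySeason:
    """Assemble the Oct 1 `start_year` → Jun 30 `start_year+1` season.

    Internal gaps of at most ``max_gap`` consecutive missing days are filled
    by linear interpolation of tmax and tmin independently.  Longer gaps, or
    a missing onset/end boundary, raise :class:`SeasonExtractionError` —
    chill accumulation is a running sum and long gaps would bias it.
    """
    onset = _dt.date(start_year, 10, 1)
    end = _dt.date(start_year + 1, 6, 30)
    by_date: dict[_dt.date, DailyTemperatureRecord] = {}
    for r in records:
        if onset <= r.date <= end:
            by_date[r.date] = r  # later duplicates win; dates are unique upstream

    n_days = (end - onset).days + 1
    dates = [onset + _dt.timedelta(days=i) for i in range(n_days)]
    present = np.array([d in by_date for d in dates])
    if not present[0]:
        raise SeasonExtractionError(f"season {season_label(start_year)}: onset {onset} missing")
    if not present[-1]:
        raise SeasonExtractionError(f"season {season_label(start_year)}: end {end} missing")

    # locate runs of missing days
    idx = np.arange(n_days)
    missing = idx[~present]
    if missing.size:
        runs: list[tuple[int, int]] = []
        run_start = int(missing[0])
        prev = int(missing[0])
        for m in missing[1:]:
            m = int(m)
            if m == prev + 1:
                prev = m
                continue
            runs.append((run_start, prev))
            run_start = prev = m
        runs.append((run_start, prev))
        for a, b in runs:
            if b - a + 1 > max_gap:
                raise SeasonExtractionError(
                    f"season {season_label(start_year)}: gap of {b - a + 1} days "
                    f"({dates[a]}..{dates[b]}) exceeds max_gap={max_gap}"
                )
        tmax = np.array([by_date[d].tmax if p else np.nan for d, p in zip(dates, present)])
        tmin = np.array([by_date[d].tmin if p else np.nan for d, p in zip(dates, present)])
        known = idx[present]
        tmax[~present] = np.interp(missing, known, tmax[present])
        tmin[~present] = np.interp(missing, known, tmin[present])
        out = [
            by_date[d]
            if p
            else DailyTemperatureRecord(d, float(tmax[i]), float(tmin[i]))
            for i, (d, p) in enumerate(zip(dates, present))
        ]
    else:
        out = [by_date[d] for d in dates]
    return DormancySeason(season_label(start_year), onset, out)


def read_observed_pbd(path: str | Path) -> list[ObservedPBD]:
    """Read a (season_start_year, bloom_date) CSV of observed PBD.

    One record per season; duplicate seasons or bloom dates outside the
    Jan–Jun window of the season's second year are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    for col in ("season_start_year", "bloom_date"):
        if col not in df.columns:
            raise KeyError(f"missing column {col!r} in {path}")
    seen: dict[int, int] = {}
    out: list[ObservedPBD] = []
    dups: list[int] = []
    for _, row in df.iterrows():
        year = int(row["season_start_year"])
        date = _dt.date.fromisoformat(str(row["bloom_date"]).strip())
        if year in seen:
            dups.append(year)
            continue
        seen[year] = 1
        out.append(ObservedPBD(year, date))
    if dups:
        raise ValueError(f"duplicate season(s) in {path}: {sorted(set(dups))}")
    return out
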