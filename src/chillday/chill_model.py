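"""Two-step chill-day / anti-chill-day phenology engine.

The flowering of temperate deciduous trees is modelled in two sequential
stages.  From a fixed dormancy onset (October 1) each day contributes
*chill days* ``Cd <= 0`` whenever temperatures sit between a 0 °C floor and
the cultivar threshold ``Tc``; their running sum ``Dc`` tracks endodormancy.
Once ``Dc`` reaches the (negative) chilling requirement ``Rc``, rest is
released and, from the following day, *anti-chill days* ``Ca >= 0``
(degree-days above ``Tc``) accumulate as ``Dh``; peak bloom is the first day
``Dh`` meets the heating requirement ``Rh``.

Daily contributions follow the single-triangle rules: the diurnal course is
idealised as a triangle between ``tmin`` and ``tmax``, and ``Cd``/``Ca`` are
the areas of that triangle falling below/above ``Tc`` (chilling bounded
below by ``max(tmin, 0)``).  Five closed-form cases cover the possible
orderings of ``0 <= Tc`` relative to ``tmin`` and ``tmax``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .weather_io import (
    DailyTemperatureRecord,
    DormancySeason,
    SeasonExtractionError,
    extract_season,
)

__all__ = [
    "ModelParams",
    "DailyChillContribution",
    "BloomPrediction",
    "daily_chill_antichill",
    "chill_contributions",
    "run_season",
    "predict_pbd_series",
    "SeriesPrediction",
]


@dataclass(frozen=True)
class ModelParams:
    """Cultivar parameter triple.

    Parameters
    ----------
    tc : float
        Base threshold temperature (°C) separating chilling from forcing.
        Must be finite and non-negative (the triangle rules assume the
        threshold sits at or above the 0 °C chilling floor).
    rc : float
        Chilling requirement in chill days; strictly negative.
    rh : float
        Heating requirement in anti-chill days; strictly positive.
    """

    tc: float
    rc: float
    rh: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.tc) or self.tc < 0:
            raise ValueError(f"tc must be finite and >= 0 °C, got {self.tc}")
        if not np.isfinite(self.rc) or self.rc >= 0:
            raise ValueError(f"rc must be negative (chill days), got {self.rc}")
        if not np.isfinite(self.rh) or self.rh <= 0:
            raise ValueError(f"rh must be positive (anti-chill days), got {self.rh}")


@dataclass(frozen=True)
class DailyChillContribution:
    """One day's chill (``cd <= 0``) and anti-chill (``ca >= 0``) units."""

    cd: float
    ca: float
    case: str  # "1".."5", "isothermal", or "subzero"


def daily_chill_antichill(tmax: float, tmin: float, tc: float) -> DailyChillContribution:
    """Chill / anti-chill contribution of a single day.

    Implements the five single-triangle cases with ``Ta = (tmax + tmin)/2``
    and a 0 °C lower bound on chilling.  Degenerate days are handled
    explicitly: isothermal days (``tmax == tmin``) collapse the triangle to
    ``cd = 0``, ``ca = max(0, Ta - tc)``; days entirely below freezing
    contribute nothing.
    """
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) < tmin ({tmin})")
    if not np.isfinite(tc) or tc < 0:
        raise ValueError(f"tc must be finite and >= 0, got {tc}")
    tn, tx = float(tmin), float(tmax)
    ta = (tx + tn) / 2.0

    if tx == tn:
        return DailyChillContribution(0.0, max(0.0, ta - tc), "isothermal")
    if tx < 0.0:
        return DailyChillContribution(0.0, 0.0, "subzero")

    span = tx - tn
    if 0.0 <= tc <= tn:
        # case 1: whole triangle above the threshold
        return DailyChillContribution(0.0, ta - tc, "1")
    if 0.0 <= tn and tc < tx:
        # case 2: threshold crosses the triangle, base above freezing
        ca = (tx - tc) ** 2 / (2.0 * span)
        return DailyChillContribution(-((ta - tn) - ca), ca, "2")
    if 0.0 <= tn:
        # case 3: whole triangle below the threshold
        return DailyChillContribution(-(ta - tn), 0.0, "3")
    if tx <= tc:
        # case 4: base below freezing, apex below the threshold
        return DailyChillContribution(-(tx**2) / (2.0 * span), 0.0, "4")
    # case 5: base below freezing, threshold inside the triangle
    ca = (tx - tc) ** 2 / (2.0 * span)
    cd = -((tx**2) / (2.0 * span) - ca)
    return DailyChillContribution(cd, ca, "5")


def chill_contributions(
    tmax: np.ndarray, tmin: np.ndarray, tc: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised daily (Cd, Ca) over temperature arrays.

    Same case logic as :func:`daily_chill_antichill`; used by the season
    runner and by calibration, where many thresholds are scanned.
    """
    tx = np.asarray(tmax, dtype=float)
    tn = np.asarray(tmin, dtype=float)
    if np.any(tx < tn):
        raise ValueError("tmax < tmin in input arrays")
    ta = (tx + tn) / 2.0
    span = tx - tn
    # guard the division; isothermal days are overwritten below
    safe_span = np.where(span > 0, span, 1.0)

    ca_cross = (tx - tc) ** 2 / (2.0 * safe_span)  # area above tc when tn/0 < tc < tx
    above0 = tx**2 / (2.0 * safe_span)  # area above 0 when tn < 0 <= tx

    cd = np.zeros_like(tx)
    ca = np.zeros_like(tx)

    case1 = (tc <= tn) & (tn >= 0)
    case2 = (tn >= 0) & (tn < tc) & (tc < tx)
    case3 = (tn >= 0) & (tx <= tc) & ~case1
    case4 = (tn < 0) & (tx >= 0) & (tx <= tc)
    case5 = (tn < 0) & (tc < tx)

    ca[case1] = (ta - tc)[case1]
    ca[case2] = ca_cross[case2]
    cd[case2] = -((ta - tn) - ca_cross)[case2]
    cd[case3] = -(ta - tn)[case3]
    cd[case4] = -above0[case4]
    ca[case5] = ca_cross[case5]
    cd[case5] = -(above0 - ca_cross)[case5]

    iso = span == 0
    if np.any(iso):
        cd[iso] = 0.0
        ca[iso] = np.maximum(0.0, ta[iso] - tc)
    subzero = tx < 0
    cd[subzero] = 0.0
    ca[subzero] = 0.0
    return cd, ca


@dataclass
class BloomPrediction:
    """Result of running one dormancy season through the model.

    ``status`` is ``"bloomed"`` when both requirements were met by the
    season horizon (June 30), ``"no-release"`` when chilling never reached
    ``rc``, and ``"no-bloom"`` when rest was released but forcing never
    reached ``rh``.
    """

    season: str
    status: str
    release_date: _dt.date | None
    pbd: _dt.date | None
    chill_trajectory: np.ndarray = field(repr=False)
    forcing_trajectory: np.ndarray = field(repr=False)

    @property
    def bloomed(self) -> bool:
        return self.status == "bloomed"


def run_season(season: DormancySeason, params: ModelParams) -> BloomPrediction:
    """Accumulate chilling then forcing over one season.

    Release is the first date whose end-of-day cumulative chill sum is
    ``<= rc``; forcing starts the following day (anti-chill days accrued
    before release are discarded) and peak bloom is the first date whose
    cumulative forcing is ``>= rh``.  Whole-day threshold crossing, no
    sub-day interpolation.
    """
    tx = np.array([r.tmax for r in season.records])
    tn = np.array([r.tmin for r in season.records])
    cd, ca = chill_contributions(tx, tn, params.tc)
    dc = np.cumsum(cd)
    n = len(dc)

    release_idx = int(np.searchsorted(-dc, -params.rc, side="left"))
    if release_idx >= n:
        return BloomPrediction(season.label, "no-release", None, None, dc, np.zeros(0))
    release_date = season.records[release_idx].date

    ca_after = ca[release_idx + 1 :]
    dh = np.cumsum(ca_after)
    bloom_off = int(np.searchsorted(dh, params.rh, side="left"))
    if bloom_off >= len(dh):
        return BloomPrediction(season.label, "no-bloom", release_date, None, dc, dh)
    pbd = season.records[release_idx + 1 + bloom_off].date
    return BloomPrediction(season.label, "bloomed", release_date, pbd, dc, dh)


@dataclass
class SeriesPrediction:
    """Per-season predictions plus seasons that failed weather QC."""

    predictions: dict[int, BloomPrediction]
    failures: dict[int, str]


def predict_pbd_series(
    records: Sequence[DailyTemperatureRecord] | Iterable[DailyTemperatureRecord],
    params: ModelParams,
    years: Sequence[int],
    max_gap: int = 3,
) -> SeriesPrediction:
    """Run the model for each requested dormancy season (by start year).

    Seasons whose weather fails extraction (gaps beyond ``max_gap``, missing
    boundaries) are reported in ``failures`` rather than silently skipped.
    """
    records = list(records)
    predictions: dict[int, BloomPrediction] = {}
    failures: dict[int, str] = {}
    for year in years:
        try:
            season = extract_season(records, year, max_gap=max_gap)
        except SeasonExtractionError as exc:
            failures[year] = str(exc)
            continue
        predictions[year] = run_season(season, params)
    if not predictions and years:
        raise SeasonExtractionError(
            f"no requested season could be assembled; failures: {failures}"
        )
    return SeriesPrediction(predictions, failures)
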