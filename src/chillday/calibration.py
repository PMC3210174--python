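"""Cultivar parameter estimation by exhaustive grid search on RMSE.

The triple (Tc, Rc, Rh) is estimated from observed peak bloom dates and
daily weather by minimising the RMSE between predicted and observed bloom
day-of-year over all dormancy seasons, on an exhaustive parameter grid,
optionally followed by local coordinate-descent refinement around the grid
optimum.  Seasons in which a candidate parameter set never releases
dormancy or never reaches the heating requirement contribute a fixed
penalty (default 60 days) as their absolute error, so parameter sets that
avoid blooming are not rewarded.

The search exploits the model structure: for a fixed Tc the daily chill and
anti-chill series of a season are fixed, so the release day is a
``searchsorted`` on the cumulative chill sum as a function of Rc, and the
bloom day a ``searchsorted`` on the cumulative forcing sum as a function of
(release day, Rh).  This makes the full default grid (~7.7 million
parameter combinations) tractable in seconds.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chill_model import ModelParams, chill_contributions, run_season
from .evaluation import FitStatistics, evaluate
from .weather_io import (
    DailyTemperatureRecord,
    DormancySeason,
    ObservedPBD,
    SeasonExtractionError,
    extract_season,
)

__all__ = [
    "GridSpec",
    "CalibrationResult",
    "CalibrationError",
    "calibrate",
    "penalized_rmse",
    "DEFAULT_PENALTY_DAYS",
]

#: absolute error charged to a season that fails to bloom, in days
DEFAULT_PENALTY_DAYS = 60.0

_TIE_TOL = 1e-9


class CalibrationError(ValueError):
    pass


def _axis_values(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    vals = lo + step * np.arange(n)
    return np.round(vals, 10)


@dataclass(frozen=True)
class GridSpec:
    """Search ranges (lo, hi, step) for Tc (°C), Rc (<0) and Rh (>0).

    The default brackets published cherry estimates with margin; the
    refinement stage recovers sub-step precision.
    """

    tc: tuple[float, float, float] = (0.0, 12.0, 0.1)
    rc: tuple[float, float, float] = (-200.0, -20.0, 1.0)
    rh: tuple[float, float, float] = (50.0, 400.0, 1.0)

    def __post_init__(self) -> None:
        for name, (lo, hi, step) in (("tc", self.tc), ("rc", self.rc), ("rh", self.rh)):
            if step <= 0:
                raise ValueError(f"{name}: step must be > 0")
            if hi < lo:
                raise ValueError(f"{name}: empty range [{lo}, {hi}]")
        if self.rc[1] >= 0:
            raise ValueError("rc range must be entirely negative")
        if self.rh[0] <= 0:
            raise ValueError("rh range must be entirely positive")
        if self.tc[0] < 0:
            raise ValueError("tc range must be non-negative")

    def tc_values(self) -> np.ndarray:
        return _axis_values(*self.tc)

    def rc_values(self) -> np.ndarray:
        return _axis_values(*self.rc)

    def rh_values(self) -> np.ndarray:
        return _axis_values(*self.rh)


@dataclass
class CalibrationResult:
    params: ModelParams
    fit: FitStatistics
    n_seasons_used: int
    seasons_dropped: list[int]  # start years failing to bloom under best params
    grid_params: ModelParams | None = None  # optimum before refinement
    trace: list[tuple[float, float]] = field(default_factory=list)  # (tc, best rmse at tc)


@dataclass
class _SeasonData:
    """Precomputed per-season arrays for the vectorised search."""

    start_year: int
    tmax: np.ndarray
    tmin: np.ndarray
    doy: np.ndarray  # continuous DOY relative to Jan 1 of the bloom year
    obs_doy: float
    season: DormancySeason


def _continuous_doy(date: _dt.date, bloom_year: int) -> float:
    return (date - _dt.date(bloom_year, 1, 1)).days + 1


def _prepare_seasons(
    observations: Sequence[ObservedPBD],
    weather: Sequence[DailyTemperatureRecord],
    max_gap: int,
) -> tuple[list[_SeasonData], dict[int, str]]:
    data: list[_SeasonData] = []
    failures: dict[int, str] = {}
    for obs in sorted(observations, key=lambda o: o.start_year):
        try:
            season = extract_season(weather, obs.start_year, max_gap=max_gap)
        except SeasonExtractionError as exc:
            failures[obs.start_year] = str(exc)
            continue
        bloom_year = obs.start_year + 1
        data.append(
            _SeasonData(
                start_year=obs.start_year,
                tmax=np.array([r.tmax for r in season.records]),
                tmin=np.array([r.tmin for r in season.records]),
                doy=np.array(
                    [_continuous_doy(r.date, bloom_year) for r in season.records],
                    dtype=float,
                ),
                obs_doy=_continuous_doy(obs.bloom_date, bloom_year),
                season=season,
            )
        )
    return data, failures


def _objective_components(
    data: Sequence[_SeasonData], params: ModelParams, penalty: float
) -> tuple[float, float, int]:
    """(sum of squared errors, sum of errors, n bloomed) at one parameter set."""
    sse = 0.0
    sum_err = 0.0
    bloomed = 0
    for s in data:
        cd, ca = chill_contributions(s.tmax, s.tmin, params.tc)
        dc = np.cumsum(cd)
        n = dc.size
        rel = int(np.searchsorted(-dc, -params.rc, side="left"))
        if rel >= n:
            sse += penalty**2
            sum_err += penalty
            continue
        cumca = np.cumsum(ca)
        idx = int(np.searchsorted(cumca, cumca[rel] + params.rh, side="left"))
        if idx >= n:
            sse += penalty**2
            sum_err += penalty
            continue
        err = s.doy[idx] - s.obs_doy
        sse += err**2
        sum_err += err
        bloomed += 1
    return sse, sum_err, bloomed


def penalized_rmse(
    params: ModelParams,
    observations: Sequence[ObservedPBD],
    weather: Sequence[DailyTemperatureRecord],
    penalty: float = DEFAULT_PENALTY_DAYS,
    max_gap: int = 3,
) -> float:
    """RMSE of predicted vs observed bloom DOY with failure penalties.

    Each season where the parameter set yields no dormancy release or no
    bloom by June 30 contributes ``penalty`` days as its absolute error.
    """
    data, _ = _prepare_seasons(observations, weather, max_gap)
    if not data:
        raise CalibrationError("no usable season (weather/observation mismatch)")
    sse, _, _ = _objective_components(data, params, penalty)
    return float(np.sqrt(sse / len(data)))


def _grid_search(
    data: Sequence[_SeasonData],
    grid: GridSpec,
    penalty: float,
) -> tuple[ModelParams, list[tuple[float, float]]]:
    tc_vals = grid.tc_values()
    rc_vals = grid.rc_values()
    rh_vals = grid.rh_values()
    n_seasons = len(data)

    best_key: tuple[float, float, float, float, float] | None = None
    best_params: tuple[float, float, float] | None = None
    trace: list[tuple[float, float]] = []
    any_release = False

    for tc in tc_vals:
        sse = np.zeros((rc_vals.size, rh_vals.size))
        sum_err = np.zeros_like(sse)
        for s in data:
            cd, ca = chill_contributions(s.tmax, s.tmin, float(tc))
            dc = np.cumsum(cd)
            cumca = np.cumsum(ca)
            n = dc.size
            rel = np.searchsorted(-dc, -rc_vals, side="left")
            released = rel < n
            if released.any():
                any_release = True
            rel_c = np.clip(rel, 0, n - 1)
            targets = cumca[rel_c][:, None] + rh_vals[None, :]
            idx = np.searchsorted(cumca, targets, side="left")
            ok = released[:, None] & (idx < n)
            pred = s.doy[np.clip(idx, 0, n - 1)]
            err = np.where(ok, pred - s.obs_doy, penalty)
            sse += np.where(ok, err**2, penalty**2)
            sum_err += err
        rmse = np.sqrt(sse / n_seasons)
        slab_min = float(rmse.min())
        trace.append((float(tc), slab_min))
        if best_key is not None and slab_min > best_key[0] + _TIE_TOL:
            continue
        # candidates tied with the slab minimum; rank by |bias|, then Rc
        # closest to zero (largest), then smallest Rh for determinism
        cand = np.argwhere(rmse <= slab_min + _TIE_TOL)
        bias = np.abs(sum_err[cand[:, 0], cand[:, 1]] / n_seasons)
        order = np.lexsort((cand[:, 1], -cand[:, 0], bias))
        i_rc, i_rh = cand[order[0]]
        key = (
            slab_min,
            float(bias[order[0]]),
            float(tc),
            -float(rc_vals[i_rc]),
            float(rh_vals[i_rh]),
        )
        if best_key is None or _key_better(key, best_key):
            best_key = key
            best_params = (float(tc), float(rc_vals[i_rc]), float(rh_vals[i_rh]))

    if not any_release:
        raise CalibrationError(
            "grid infeasible: no grid point releases dormancy in any season"
        )
    assert best_params is not None
    return ModelParams(*best_params), trace


def _key_better(a: tuple, b: tuple) -> bool:
    """Lexicographic with tolerance on the RMSE and bias components."""
    for i, (x, y) in enumerate(zip(a, b)):
        tol = _TIE_TOL if i < 2 else 0.0
        if x < y - tol:
            return True
        if x > y + tol:
            return False
    return False


def _refine(
    data: Sequence[_SeasonData],
    start: ModelParams,
    grid: GridSpec,
    penalty: float,
) -> ModelParams:
    """Coordinate descent around the grid optimum, halving steps.

    Each dimension starts at its grid step; steps are halved whenever a
    full sweep yields no improvement, until every step has shrunk below
    5 % of its grid step.
    """
    steps = np.array([grid.tc[2], grid.rc[2], grid.rh[2]], dtype=float)
    stop = 0.05 * steps
    cur = np.array([start.tc, start.rc, start.rh], dtype=float)

    def obj(v: np.ndarray) -> float:
        try:
            p = ModelParams(*v)
        except ValueError:
            return np.inf
        sse, _, _ = _objective_components(data, p, penalty)
        return float(np.sqrt(sse / len(data)))

    cur_val = obj(cur)
    while np.any(steps >= stop):
        improved = False
        for dim in range(3):
            if steps[dim] < stop[dim]:
                continue
            for sign in (+1.0, -1.0):
                trial = cur.copy()
                trial[dim] += sign * steps[dim]
                val = obj(trial)
                if val < cur_val - _TIE_TOL:
                    cur, cur_val = trial, val
                    improved = True
        if not improved:
            steps = steps / 2.0
    return ModelParams(*np.round(cur, 10))


def calibrate(
    observations: Sequence[ObservedPBD],
    weather: Sequence[DailyTemperatureRecord],
    grid: GridSpec | None = None,
    refine: bool = True,
    penalty: float = DEFAULT_PENALTY_DAYS,
    max_gap: int = 3,
    keep_trace: bool = False,
) -> CalibrationResult:
    """Estimate (Tc, Rc, Rh) from observed PBD and daily weather.

    Exhaustively evaluates the grid, breaking RMSE ties by smallest |bias|,
    then smallest Tc, then Rc closest to zero; optionally refines the grid
    optimum by coordinate descent.  Deterministic given inputs and
    invariant to the ordering of the observations.
    """
    grid = grid or GridSpec()
    data, _failures = _prepare_seasons(observations, weather, max_gap)
    if len(data) < 3:
        raise CalibrationError(
            f"need >= 3 seasons with both weather and observed PBD, got {len(data)}"
        )
    grid_best, trace = _grid_search(data, grid, penalty)
    best = _refine(data, grid_best, grid, penalty) if refine else grid_best

    pred, obs, dropped = [], [], []
    for s in data:
        result = run_season(s.season, best)
        if result.bloomed:
            assert result.pbd is not None
            pred.append(_continuous_doy(result.pbd, s.start_year + 1))
            obs.append(s.obs_doy)
        else:
            dropped.append(s.start_year)
    if not pred:
        raise CalibrationError("best parameters bloom in no season")
    fit = evaluate(pred, obs)
    return CalibrationResult(
        params=best,
        fit=fit,
        n_seasons_used=len(pred),
        seasons_dropped=dropped,
        grid_params=grid_best,
        trace=trace if keep_trace else [],
    )
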