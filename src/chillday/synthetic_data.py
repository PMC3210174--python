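"""Synthetic daily weather and bloom observations for end-to-end testing.

The weather generator emulates a mid-latitude station series of the kind
the model is normally driven by (airport daily summaries): a sinusoidal
annual cycle in the daily mean, first-order autoregressive (AR(1)) daily
anomalies so that chill sums see realistic day-to-day persistence, and a
jittered diurnal range split symmetrically into Tmax/Tmin.  Defaults are a
Washington-DC-like climate: annual mean 12 °C, amplitude 12 °C (January
mean ≈ 0 °C, July ≈ 24 °C), coldest around mid-January, 9 °C mean diurnal
range.

Bloom observations are generated by running the forward model with known
"true" parameters and adding rounded Gaussian noise to the bloom day of
year, which makes full-pipeline parameter-recovery tests possible without
any external data.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chill_model import ModelParams, predict_pbd_series
from .weather_io import DailyTemperatureRecord, ObservedPBD

__all__ = [
    "SyntheticWeatherConfig",
    "SyntheticPBDConfig",
    "generate_weather",
    "generate_pbd",
]


@dataclass(frozen=True)
class SyntheticWeatherConfig:
    """Parameters of the synthetic station climate.

    ``phase_doy`` is the day of year of the annual temperature minimum.
    ``noise_sd`` is the standard deviation of the AR(1) innovations, so the
    marginal anomaly spread is ``noise_sd / sqrt(1 - rho**2)``.
    """

    mean: float = 12.0  # annual mean of daily mean temperature, °C
    amplitude: float = 12.0  # annual half-range, °C
    phase_doy: float = 15.0  # DOY of the annual minimum
    diurnal_range: float = 9.0  # mean Tmax − Tmin, °C
    rho: float = 0.8  # AR(1) coefficient of daily anomalies
    noise_sd: float = 2.5  # innovation sd, °C (marginal anomaly sd ≈ 4.2 °C)
    n_years: int = 20  # number of dormancy seasons covered
    start_year: int = 1991  # first season start year
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.diurnal_range <= 0:
            raise ValueError("diurnal range must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.n_years < 1:
            raise ValueError("need at least one year")


@dataclass(frozen=True)
class SyntheticPBDConfig:
    """Forward-model truth and observation noise for synthetic PBD."""

    params: ModelParams
    noise_sd: float = 0.0  # days
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def generate_weather(config: SyntheticWeatherConfig) -> list[DailyTemperatureRecord]:
    """Daily Tmax/Tmin series covering ``n_years`` dormancy seasons.

    The series runs from Jan 1 of ``start_year`` through Dec 31 of
    ``start_year + n_years`` so seasons starting Oct 1 of years
    ``start_year .. start_year + n_years − 1`` are fully covered.  The
    daily mean follows ``mean − amplitude·cos(2π(d − phase)/365.25)`` on a
    continuous day axis plus AR(1) anomalies; the diurnal range is jittered
    around its mean with a 0.5 °C floor.  Deterministic under the seed;
    ``noise_sd = 0`` switches off all stochasticity (anomalies and range
    jitter alike), giving a pure sinusoidal series.
    """
    rng = np.random.default_rng(config.seed)
    first = _dt.date(config.start_year, 1, 1)
    last = _dt.date(config.start_year + config.n_years, 12, 31)
    n = (last - first).days + 1
    d = np.arange(n, dtype=float) + first.timetuple().tm_yday  # continuous day axis

    ta = config.mean - config.amplitude * np.cos(
        2.0 * np.pi * (d - config.phase_doy) / 365.25
    )
    if config.noise_sd > 0:
        innov = rng.normal(0.0, config.noise_sd, size=n)
        noise = np.empty(n)
        # start the chain at its stationary distribution
        noise[0] = innov[0] / np.sqrt(1.0 - config.rho**2)
        for i in range(1, n):
            noise[i] = config.rho * noise[i - 1] + innov[i]
        ta = ta + noise
    if config.noise_sd > 0:
        jitter = rng.normal(0.0, 0.15 * config.diurnal_range, size=n)
    else:
        jitter = np.zeros(n)
    ranges = np.maximum(0.5, config.diurnal_range + jitter)
    tmax = ta + ranges / 2.0
    tmin = ta - ranges / 2.0
    return [
        DailyTemperatureRecord(first + _dt.timedelta(days=i), float(tmax[i]), float(tmin[i]))
        for i in range(n)
    ]


def generate_pbd(
    weather: Sequence[DailyTemperatureRecord], config: SyntheticPBDConfig
) -> list[ObservedPBD]:
    """Observed PBD = forward-model PBD + rounded Gaussian noise (days).

    One observation per coverable dormancy season.  Any season where the
    true parameters fail to bloom is an error: synthetic truth must bloom
    everywhere so recovery tests are well posed.
    """
    weather = list(weather)
    if not weather:
        raise ValueError("weather series is empty")
    years = _coverable_start_years(weather)
    if not years:
        raise ValueError("weather covers no complete dormancy season")
    result = predict_pbd_series(weather, config.params, years)
    failed = sorted(set(years) - set(result.predictions)) + [
        y for y, p in result.predictions.items() if not p.bloomed
    ]
    if failed:
        raise ValueError(
            f"true parameters fail to bloom in season(s) starting {sorted(failed)}"
        )
    rng = np.random.default_rng(config.seed)
    out = []
    for year in years:
        pbd = result.predictions[year].pbd
        assert pbd is not None
        offset = int(round(rng.normal(0.0, config.noise_sd))) if config.noise_sd > 0 else 0
        date = pbd + _dt.timedelta(days=offset)
        out.append(ObservedPBD(year, date))
    return out


def _coverable_start_years(weather: Sequence[DailyTemperatureRecord]) -> list[int]:
    dates = {r.date for r in weather}
    first = min(dates)
    last = max(dates)
    years = []
    for y in range(first.year - 1, last.year + 1):
        if _dt.date(y, 10, 1) in dates and _dt.date(y + 1, 6, 30) in dates:
            years.append(y)
    return years
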