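# chillday

Process-based prediction of cherry peak bloom dates (PBD) from daily
temperatures, for phenologists and horticultural planners studying how
warming shifts spring flowering.

Flowering of temperate deciduous trees such as the Tidal Basin cherries
(*Prunus × yedoensis* 'Yoshino', *Prunus serrulata* 'Kwanzan') is modelled
in two sequential stages. From a fixed dormancy onset (October 1), each day
contributes **chill days** `Cd ≤ 0` computed from (`Tmax`, `Tmin`) by the
single-triangle rules: the diurnal temperature course is idealised as a
triangle between `Tmin` and `Tmax`, and `Cd` is minus the triangle area
lying between a 0 °C floor and the cultivar threshold `Tc`. When the running
sum `Dc = Σ Cd` reaches the chilling requirement `Rc` (< 0), endodormancy is
released; from the next day, **anti-chill days** `Ca ≥ 0` (triangle area
above `Tc`) accumulate as `Dh = Σ Ca`, and peak bloom is the first day
`Dh ≥ Rh`, the heating requirement. The cultivar triple `(Tc, Rc, Rh)` is
estimated from observed PBD by exhaustive grid search minimising RMSE (with
a 60-day penalty for parameter sets that fail to bloom), followed by local
coordinate-descent refinement.

For climate projections, 30-year monthly `Tmax`/`Tmin` normals are
temporally downscaled to a 365-day daily "normal year" by exact
trigonometric interpolation (mean + 5 harmonics + Nyquist cosine anchored
at mid-month days of year), wrapped into an Oct 1 → Jun 30 season and run
through the same engine; reports give projected mean PBD per location ×
scenario × period, advancement versus an observed baseline, and
cross-location spreads.

## Worked example

A fully synthetic round trip — simulate 20 seasons of station-like weather
plus bloom observations with 2-day observation noise, then re-estimate the
cultivar parameters:

```
$ chillday simulate --seed 42 --years 20 --noise-sd 2 --tc 5 --rc -90 --rh 220 --out sim/
$ chillday calibrate --weather sim/weather.csv --pbd sim/pbd.csv --out cal/
{"tc": 4.0, "rc": -89.0, "rh": 258.0}
```

`cal/calibration.json` holds the fit: RMSE 1.05 days, MAE 0.6, bias 0.0,
r² 0.995 over n = 20 seasons. The refit reproduces the bloom dates to about
a day; the triple itself sits in the shallow valley typical of this model
(`Tc` recovered 4.0 vs true 5.0, `Rc` −89 vs −90, `Rh` 258 vs 220) because
with day-resolution observations different triples can predict nearly
identical bloom dates (see `docs/methods.md`).

Projection with published Yoshino parameters `(Tc, Rc, Rh) =
(4.3, −78.9, 221.2)` on toy warming normals (+1.0, +2.0, +3.2 °C for the
2020s/2050s/2080s over a DC-like annual cycle), against an April 2
baseline:

```python
cells, summary = project({"yoshino": ModelParams(4.3, -78.9, 221.2)}, normals,
                         {"yoshino": BaselinePBD("yoshino", date(2001, 4, 2))})
```

```
cultivar    location scenario period pbd_date  pbd_doy  advancement_days
 yoshino tidal_basin      A1B  2020s    03-30       89                 3
 yoshino tidal_basin      A1B  2050s    03-24       83                 9
 yoshino tidal_basin      A1B  2080s    03-17       76                16
```

Bloom advances by days-per-degree of warming, as expected for a
forcing-dominated spring phenophase.

CLI subcommands: `simulate`, `calibrate`, `predict`, `evaluate`,
`downscale`, `project`; each writes a `manifest.json` echoing its effective
configuration and seed.

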