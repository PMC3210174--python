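# Methods

## The two-step chill-day model

The model splits flowering into endodormancy (rest) and floral forcing.
Daily air temperature enters only through `Tmax`, `Tmin` and the derived
mean `Ta = (Tmax + Tmin)/2`; the diurnal course is idealised as a single
triangle from `Tmin` up to `Tmax` and back. With a cultivar threshold `Tc`
and a 0 °C lower bound, the day's anti-chill contribution `Ca` is the
triangle area above `Tc` and the chill contribution `Cd` is minus the area
between `max(Tmin, 0)` and `Tc`. Writing `Tn = Tmin`, `Tx = Tmax`, the
closed forms by ordering of `0 ≤ Tc` against `Tn, Tx` are:

| case | predicate | Cd | Ca |
|---|---|---|---|
| 1 | `0 ≤ Tc ≤ Tn ≤ Tx` | `0` | `Ta − Tc` |
| 2 | `0 ≤ Tn ≤ Tc < Tx` | `−[(Ta − Tn) − Ca]` | `(Tx − Tc)² / 2(Tx − Tn)` |
| 3 | `0 ≤ Tn ≤ Tx ≤ Tc` | `−(Ta − Tn)` | `0` |
| 4 | `Tn < 0 ≤ Tx ≤ Tc` | `−Tx² / 2(Tx − Tn)` | `0` |
| 5 | `Tn < 0 ≤ Tc < Tx` | `−[Tx²/2(Tx − Tn) − Ca]` | `(Tx − Tc)² / 2(Tx − Tn)` |

Degenerate inputs are handled as continuity limits: isothermal days
(`Tx = Tn`) give `Cd = 0`, `Ca = max(0, Ta − Tc)`; days entirely below
freezing contribute nothing. The formulas are continuous across every case
boundary, and the test suite checks them against an independent numerical
integration of the triangular diurnal course (agreement ≤ 1e−3 chill days
over 10⁴ random inputs).

Accumulation is strictly sequential. `Dc = Σ Cd` runs from the dormancy
onset, fixed at October 1 (autumn dormancy-induction processes are not
modelled). Release is the first date whose end-of-day `Dc ≤ Rc`; threshold
crossing is whole-day — no sub-day interpolation — because bloom records
are calendar dates. Forcing starts the day *after* release; any anti-chill
accumulated before release is discarded. Peak bloom is the first date with
`Dh = Σ Ca ≥ Rh`. Seasons are evaluated to June 30; a season that never
reaches `Rc` is flagged `no-release`, one that releases but never reaches
`Rh` is `no-bloom`. Whether the release day itself should count toward
forcing, and whether chilling continues during forcing, are not observable
at day resolution; this implementation starts forcing the next day and
freezes `Dc` at release.

Published cultivar estimates used in examples and as input parameters:
Yoshino (4.3 °C, −78.9, 221.2), Kwanzan (5.3 °C, −114.0, 289.1), and the
Korean *P. serrulata* var. *spontanea* (7.0 °C, −110.0, 123.5).

## Weather handling

Daily CSVs are screened, not silently corrected: rows with unparseable
dates, non-numeric or implausible (|T| > 60 °C) temperatures, or
`Tmax < Tmin` are excluded and reported with line numbers. Seasons are
assembled from October 1 through June 30 (273 days, 274 over a leap
spring). Internal gaps of at most 3 consecutive days are filled by linear
interpolation of `Tmax` and `Tmin` independently; longer gaps or missing
boundary days reject the season with a diagnostic, because chill
accumulation is a running sum and long gaps would bias it. Gap filling
never alters observed days. How the original station records handled
missing days is unknown; this policy is the package's own.

## Calibration

`(Tc, Rc, Rh)` is estimated by minimising the RMSE between predicted and
observed bloom day-of-year over an exhaustive grid, default
`Tc ∈ [0, 12] × 0.1 °C`, `Rc ∈ [−200, −20] × 1`, `Rh ∈ [50, 400] × 1`
(brackets the published cherry estimates with margin). A season in which a
candidate triple fails to bloom contributes a fixed 60-day absolute error —
discarding such seasons would reward parameter sets that avoid blooming.
Ties in RMSE are broken by smallest |bias|, then smallest `Tc`, then `Rc`
closest to zero, then smallest `Rh`, making the result deterministic and
order-invariant. The grid optimum is refined by coordinate descent, halving
all three steps whenever a sweep fails to improve, until each step is below
5 % of its grid step.

The search is exact, not heuristic: for fixed `Tc` the daily contributions
of a season are fixed, so release day is a binary search on the cumulative
chill sum as a function of `Rc`, and bloom day a binary search on the
cumulative forcing sum — the full ~7.7-million-point default grid over 20
seasons evaluates in a few seconds on one core.

**Identifiability.** The objective is piecewise constant: predictions move
in whole days, so a connected set of triples can fit identically. With
noise-free observations over 20 sufficiently variable winters this set
collapses to (essentially) the generating triple, and the suite verifies
exact recovery. With 2-day observation noise the minimum sits in a long
shallow valley — `Rc` and `Rh` trade off against `Tc`, and the objective at
the generating truth is within ~0.2 days of the optimum — so
single-replicate `Rc`/`Rh` estimates scatter by roughly ±10–25 units while
predicted bloom dates barely change. The recovery test therefore asserts
per-replicate accuracy for `Tc` (within 1 °C) and accuracy of the
*replicate mean* over 5 seeds for the triple (within 1 °C, 10 chill days,
15 anti-chill days): a bias check, which is what noisy data can support.
This mirrors the field experience that chill/heat requirements from bloom
records alone are weakly identified even when predictions are excellent.

## Fit statistics

Errors are `e = predicted − observed` DOY, so positive bias = model late.
`RMSE = √(Σe²/n)`, `MAE = Σ|e|/n`, `bias = Σe/n`; `r²` is the squared
Pearson correlation of predictions with observations (the common phenology
convention, not 1 − SSE/SST), undefined (NaN) when either series is
constant. These satisfy `RMSE² = bias² + Var(e)` (population variance) and
`RMSE ≥ MAE ≥ |bias|`; both are enforced by property tests. A published
evaluation subset reporting MAE greater than RMSE is arithmetically
impossible under these definitions (almost certainly a transposition) and
is not targeted.

## Temporal downscaling of monthly normals

Monthly normals carry no leap-day identity, so the normal year has 365
days. The 12 monthly values are anchored at mid-month DOYs (15, 46, 74,
105, 135, 166, 196, 227, 258, 288, 319, 349) and interpolated by the exact
trigonometric polynomial on period 365 — mean, harmonics k = 1..5 (sine and
cosine) and the k = 6 Nyquist cosine — solved as a 12 × 12 linear system.
Exact interpolation was chosen over a truncated least-squares harmonic fit
because it is deterministic, passes through every anchor (≤ 1e−6), nests
lower-order fits, and preserves constants and single harmonics identically.
Monthly means of the interpolated curve are close to, but not exactly, the
inputs (within 0.5 °C for smooth annual cycles); exact mean preservation is
not claimed. `Tmax` and `Tmin` are interpolated independently; days where
the curves cross are set to their common midpoint and counted in a
diagnostic. The normal year is wrapped into an Oct 1 → Jun 30 season on a
nominal non-leap year pair (2001/2002) for the engine.

## Projection reporting

All table arithmetic uses the non-leap DOY mapping (March 1 = 60).
Advancement is baseline DOY − projected DOY, positive = earlier.
Cross-location spread is the sample (n−1) standard deviation of DOYs,
reported to one decimal; this convention reproduces the published
cross-location SD row entries from the printed city dates (one printed
entry disagrees with its own dates by ~0.4 days and is excluded from
checks, as are the per-city cross-period SD columns, whose convention does
not match either the sample or population formula). The per-period mean
PBD of a normal period is the single prediction on that period's
downscaled climatology, not a mean over resampled years, since normals are
run directly. Cells whose climatology fails to release or bloom are
flagged in the output, never dropped; projected DOYs outside February–June
are marked anomalous.

## Synthetic data

The generator emulates a mid-latitude station series: daily mean
`Ta(d) = mean − amplitude·cos(2π(d − phase)/365.25)` plus AR(1) anomalies,
split into `Tmax/Tmin` by a jittered diurnal range (floor 0.5 °C). Defaults
are DC-like: mean 12 °C, amplitude 12 °C, minimum at DOY 15, diurnal range
9 °C, AR(1) ρ = 0.8 with innovation sd 2.5 °C (marginal anomaly sd
≈ 4.2 °C, matching observed winter daily-mean variability and lag-1
autocorrelation of mid-Atlantic stations), 20 seasons. The 365.25-day
sinusoid keeps multi-year calendar alignment without special-casing leap
years. `noise_sd = 0` disables all stochasticity, giving a pure sinusoid.
Synthetic observations are forward-model bloom dates plus rounded Gaussian
noise, and fail loudly if the truth parameters do not bloom in every
season.

What the generator does *not* emulate: synoptic cold spells with skewed
anomaly distributions, inter-annual regime shifts (ENSO/NAO), urban-heat
or coastal effects, missing-data patterns of real stations, and
observer error structure in bloom records (which is neither Gaussian nor
independent across years). Passing recovery tests therefore demonstrates
correctness and statistical behaviour of the estimator under the assumed
conditions, not performance on real station archives.

## Problem sizes and determinism

Test-suite simulations use 20 seasons for calibration checks (5 noisy
replicates), 3–5 seasons for engine properties, 10⁴ random inputs for the
oracle comparison, and the full default grid for recovery runs; the whole
suite runs in well under a minute on one core. Every stochastic component
is driven by an explicit integer seed through `numpy.random.default_rng`;
identical configurations are byte-identical across runs.

## Known limitations

- Dormancy onset is fixed at October 1; autumn warming effects on
  dormancy induction are outside the model.
- Photoperiod and precipitation are ignored (cherries are weakly sensitive
  or insensitive to both).
- No parameter uncertainty intervals are produced; given the
  identifiability structure above, bootstrap intervals on `(Rc, Rh)` would
  be wide and strongly correlated.
- Spatial downscaling of climate projections is out of scope: monthly
  normals are consumed as given, on toy location sets.
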