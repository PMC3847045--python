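# Methods

## Scope and data model

`meteotrigger` analyses the relation between discrete event days (the
motivating case: aneurysmal SAH symptom-onset days in a single catchment
region) and hourly meteorological station records. All timestamps are UTC and
a "day" is the UTC calendar day; weather timestamps label the start of the
hour. The canonical formats are two CSVs: a wide hourly weather table (one
row per station-hour, empty cell = missing) and an event list (one row per
patient, duplicate dates allowed). Values are written at measurement
precision — one decimal for temperature, pressure, gusts and precipitation,
whole numbers for relative humidity and sunshine minutes — so a write/read
round trip is exact.

## Daily metrics

Each day is characterized by a single value per parameter: arithmetic mean
over available hours for temperature, surface pressure and relative humidity;
maximum for wind gusts; daily sum for precipitation (mm/day); and the sum of
sunshine minutes over the five hourly intervals starting 10:00–14:00 UTC
(half-open [10:00, 15:00), maximum 300 min). The fixed UTC window makes
sunshine comparable across the seasonal daylight shift. The window is taken
half-open; including the 15:00 hour would be an equally defensible reading of
"between 10 and 15 UTC", and the choice is documented rather than claimed.

Completeness rules: mean and max metrics require ≥ 20 of 24 hourly values;
the precipitation sum requires ≥ 20 hours and treats missing hours as 0 mm
(a deliberate conservative under-count, logged); sunshine requires all five
window hours. A day failing its rule is *missing*, never zero, and missing
days are excluded downstream — no interpolation or imputation anywhere.

## Climatology and anomalies

The climatological baseline is the plain arithmetic mean of the daily metric
per calendar month over a multi-year reference period — ten whole years by
default, configurable; no harmonic smoothing across months, because the
statistic is explicitly a *monthly* climatology. Building it requires ≥ 28
usable daily values in every calendar month. An anomaly is a day's metric
minus its month's mean; within the reference period the anomalies of each
month sum to zero by construction, which the tests assert to floating
tolerance. The climatology averages daily metrics (not hourly values) so that
climatology, anomaly and test statistic all operate on the same daily object.

## Epoch profiles

For each event day $d$ and offset $k \in \{-5,\dots,+5\}$ the difference
$x_{d+k} - x_d$ is collected; offset 0 is identically zero. Missing data are
handled pairwise per offset, so one missing day does not discard the event.
Events within five days of the daily series' boundary are excluded from this
analysis only, with a logged count. Offsets are summarized by n, mean,
quartiles and 1.5×IQR whiskers (the whisker convention is a package choice).
The profile is descriptive; no significance test is attached.

## Event statistics and the resampling null

Two per-event statistics are defined. The *climatology anomaly* is the
anomaly on the event day. The *two-day change* is the event-day metric minus
its value on a baseline day: normally $d-2$, but if that day (or further
candidates) is itself an event day the baseline walks backward until it finds
an event-free, non-missing day, so the comparison is always against non-event
weather. The walk is capped at a 7-day lookback; events without an eligible
baseline are excluded and counted, and more than 50% exclusions abort the
analysis. Duplicate event dates contribute once per patient (matching a
cohort-sized n rather than a day count). No seasonal correction is needed for
the two-day change since it is a short difference.

Significance uses a Monte Carlo re-sampling null of B = 1000 replicates
(configurable, B ≥ 100). Each replicate draws random days from the sampling
period — by default the whole calendar years inside the study period — with
**exactly** the observed calendar-month frequencies: within each month, days
are drawn uniformly without replacement from that month's pool across all
years (a with-replacement option exists for sensitivity analysis, and an
option to exclude the actual event days from the pool; by default they remain
eligible). Days whose required metric is missing are never eligible. The mean
statistic is recomputed on each drawn set, with the two-day-change baseline
rule applied against the drawn set itself for symmetry with the observed
statistic. Month-frequency matching is asserted on every draw.

`p_right` is the fraction of null means ≥ the observed mean (ties counted in
the tail, the conservative convention); `p_left` mirrors it, and the
two-sided p is `min(1, 2·min(p_left, p_right))`. Significance is declared
when the observed mean lies outside the empirical 5th–95th percentile band of
the null means (type-7 interpolated order statistics), a 10% two-sided level.
For plotting, null means and observed mean can be shifted by −median(null),
which preserves `p_right` exactly. No multiple-testing correction is applied
across the parameters × stations × kinds grid; the report simply lists every
p-value.

Seasonal splits: cold = Oct–Mar, warm = Apr–Sep (a documented convention —
"winter/summer" has no universal boundary). The split partitions the events
exactly; for the two-day change, the set of days treated as event days by the
baseline rule is *not* season-filtered, since a preceding day occupied by an
out-of-season event is still an event day.

## Cohort and seasonality descriptives

The cohort table reports counts and percentages (100·count/n, rounded
half-up to one decimal) for sex, circulation, GCS bands 13–15/9–12/3–8,
Hunt & Hess 1–5, Fisher 1–4, WFNS 1–5, plus mean and range of age. Half-up
rounding is used throughout; where a published table's printed value differs
by one ulp from the recomputed one (e.g. 123/511 = 24.07% printing as 24.0
under truncation), the package reports its own half-up value (24.1) rather
than silently matching. Seasonality counts events per (year, month) and
pooled per month over a whole-year window, defaulting to the first through
last full calendar year of the study period.

## The synthetic generator

The generator reproduces the statistical texture that the pipeline is
sensitive to, not physical weather. Per station and hour:

* **temperature** = μ_T + A_y·cos(2π(doy−200)/365.25) +
  A_d·cos(2π(hod−14)/24) + a_day + ε_hour, with a stationary daily AR(1)
  anomaly a_day (coefficient ρ, marginal sd σ) shared by all hours of the day
  so that daily means inherit the intended day-to-day autocorrelation.
  Defaults (μ_T = 9.3 °C, A_y = 9.5 °C, A_d = 3.5 °C, ρ = 0.75, σ = 2.8 °C)
  emulate a mid-latitude lowland station; phases 200 (doy) and 14 (hod UTC)
  put the maxima in late July and mid-afternoon.
* **pressure**: station-level mean 965 hPa + daily AR(1) (ρ = 0.85,
  σ = 7 hPa) + small hourly noise.
* **precipitation**: hourly two-state wet/dry Markov chain (p_wd = 0.055,
  p_ww = 0.62 → ≈13% wet hours in spells) with Gamma wet-hour amounts.
* **humidity**: wet-day vs dry-day level (86% vs 68%) + daily and hourly
  noise, clamped to [0, 100].
* **gusts**: log-normal with location coupled (0.35 per sd) to a shared
  AR(1) "storminess" state.
* **sunshine**: zero outside a day-of-year daylight window (half-width 4–8 h
  around 12 UTC, so the 10–15 UTC analysis window is always daylight);
  inside, a Beta fraction of 60 min, cloudier on wet days.

Stations share daily innovations with mixing weight 0.8 (shared) versus
√(1−0.8²) (own), giving the strong cross-site correlation seen between
neighbouring stations. Missingness is i.i.d. per parameter per hour (default
2%). Outputs are rounded to measurement precision. Determinism: one seed
drives everything; per-station streams are derived from it.

Event days are drawn i.i.d. from P(d) ∝ exp(β·z_d), where z_d is the
standardized coupled quantity — the daily anomaly, or its 2-day difference —
so β is a log relative risk per standard deviation and β = 0 is the exact
null. The exponential link is the simplest monotone choice given that no
mechanism is posited. Optional clinical attributes are filled from fixed
marginal frequencies typical of a large single-center SAH cohort (66.5%
female, mean age 53, etc.). What the generator does **not** emulate: weather
fronts, pressure–wind covariance beyond the shared storminess state, spatial
gradients, reporting artifacts in onset dates. Passing tests therefore show
that the *statistics* behave correctly (calibration, power, invariances), not
that any particular real-world effect exists or is absent.

## Numerical choices and degenerate inputs

Quantiles everywhere are numpy's default linear (type-7) interpolation.
Percentages use decimal half-up rounding, not banker's rounding. The AR(1)
recursion starts from its stationary distribution. Weight normalisation in
the event sampler subtracts the max log-weight before exponentiating
(overflow-safe for extreme β). Validation errors name the offending line,
row, field or month. Empty series round-trip as header-only files; an all-
missing day yields a missing metric; a month with fewer than 28 usable
reference days, a null pool smaller than the required monthly count, or a
replicate losing all days abort with explicit errors rather than degrading.

## Validation scale

The type-I/power studies run scaled-down worlds: one station, a 7-year
period (2005–2011) serving simultaneously as weather period, climatology
reference and sampling period, 100 events, B = 500, temperature/climatology-
anomaly statistic; 200 worlds for calibration and 50 per β for power. These
sizes were chosen as the smallest at which binomial error on a 10% rejection
rate is informative; the calibration property itself does not depend on the
scale. The acceptance script additionally runs one paper-scale world (511
events, 10-year reference, B = 1000).

## Known limitations

* The monthly climatology is a step function; anomalies near month
  boundaries carry a small seasonal residual that the frequency-matched null
  absorbs but the raw anomaly histogram displays.
* The null samples distinct days within a month but the observed sample may
  contain duplicate dates; with-replacement draws are available to probe
  this asymmetry.
* Calendar-month pools ignore year-to-year climate drift over the reference
  decade; no detrending is applied.
* The two-day-change baseline rule on null replicates treats drawn days as
  events; other conventions (never shifting on null draws) are defensible
  and would change null spreads slightly.
* p-values from B replicates have resolution 1/B; reported significance at
  the 10% two-sided level inherits Monte Carlo noise of order ±1/√B.
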