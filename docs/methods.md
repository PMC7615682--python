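# Methods

This note records the scientific model the package implements, the choices
made where the design was genuinely open, and what the synthetic test world
does and does not demonstrate about real data.

## Exposure metric

MDA8 is computed over all 24 start-hour windows of a calendar day, with
windows allowed to cross midnight and attributed to their start day.  A
window mean is valid when at least 6 of its 8 hours are present; a day is
reported when at least 18 of its 24 windows are valid (both thresholds
configurable).  These completeness rules follow common air-quality
practice; no single convention is universal, so the implementation is
checked against an exhaustive brute-force enumeration rather than against
an external standard.  The ppb→µg/m³ conversion uses a constant factor of
1.96, the conventional surface-conditions value for ozone; no
temperature/pressure dependence is modelled.

Cities take the hourly series of the grid cell whose bounds contain their
coordinates, with boundary ties resolved toward the lower-index cell and no
horizontal interpolation.  Cities with multiple monitors are assumed to
have been averaged upstream into one observed series.

## Bias correction

The correction is additive quantile mapping per city × calendar month:
bias b_m(q) = Q_obs(q) − Q_mod(q) on a probability grid, fitted on paired
observed/model days pooled across the training years (≥ 30 paired days per
month required; Feb 29 pools into February).  Choices the literature leaves
open, fixed here:

* **Grid.** 101 equally spaced probabilities (0, 0.01, …, 1), augmented
  with the training sample's plotting positions i/(n−1).  The augmentation
  makes the map interpolate the training quantiles exactly, so correcting
  the training model series reproduces the observed monthly quantile
  function to floating-point precision — a property the test suite asserts
  at 1e−9.
* **Probability assignment.** A new value's probability is the
  interpolated empirical CDF of its month's training *model* distribution;
  values beyond the training range receive p = 0 or 1, i.e. the bias is
  extended as a constant.  Constant extension is the most conservative
  common choice when future values exceed historical extremes.
* **Additive, not multiplicative.** Model biases are reported in
  concentration units, and an additive map preserves them exactly in the
  pure-shift limit.  Detrended or delta-change variants are out of scope.
* Corrected values below zero are clipped to zero and counted in the log.
  The additive map is order-preserving whenever the observed quantile
  function is nondecreasing (always, for empirical quantiles); a runtime
  check still logs any violation.

Monthly biases are assumed stationary between the training window and the
future period.  Each ensemble member is corrected individually; members
are averaged afterwards.

## Baseline mortality and scaling

Observed daily death counts over the training years are collapsed into a
per-city day-of-year climatology (mean per calendar day; Feb 29 falls back
to Dec 31's neighbour when absent).  Each projection day is paired with its
day-of-year baseline and scaled by the country-level factors
ΔY_b · ΔPOP for the scenario and period.  This convention lets a
three-year mortality record supply the baseline for five-year
concentration windows in both periods symmetrically; it assumes the
within-year mortality profile is stable, which is adequate for a
seasonal-baseline process but ignores secular trends within the training
window.  Scaled counts stay fractional; rounding would bias small cities.
Age structure enters only through the aggregate rate ratio — age-specific
exposure-response is a known limitation, not modelled.

## Burden, pooling and uncertainty

AF = 1 − exp(−β·C) with C the MDA8 excess above the 70 µg/m³ background
threshold; days at or below threshold contribute AF = 0 but stay in the
total-death denominator.  β is country-level, applied to all of the
country's cities, converted from RR per 10 µg/m³ as log(RR)/10.  An
optional guideline filter restricts the ADD sum to days above a stricter
concentration (e.g. 100 µg/m³) for sensitivity analyses.

Burdens are computed per model first and pooled as the arithmetic mean
(medians would be an alternative; the mean is the package default and
configurable at the call site).  Monte Carlo uncertainty draws 1,000
coefficients per country from Normal(β, se); draw-level burdens from all
models are pooled into one empirical distribution whose quantiles give the
interval.  The default level is 95%, with any level available — analyses in
this literature report both 90% and 95% intervals.  Negative coefficient
draws are evaluated as-is, so intervals can reach or cross zero; only point
estimates are guaranteed non-negative.  The change interval subtracts the
present-period mean from the future-period bounds, a translation rule that
ignores present-period uncertainty by construction.

## Driver decomposition

Climate/emissions are isolated first by evaluating the future-ozone burden
under present-period demography (B_fp); because the burden is exactly
proportional to ΔY_b·ΔPOP, the remainder splits in closed form:
population = B_fp·(r_pop − 1), rates = B_fp·r_pop·(r_rate − 1), with r the
future/present factor ratios.  The rate term is computed as the arithmetic
remainder so the three components sum to the total change to the last bit.
The ΔPOP×ΔY interaction is assigned to the rate term (applied last); the
allocation is order-dependent and the chosen order (climate → population →
rates) is a documented convention, not a unique answer.  Percent
contributions are relative to the present-period burden.

## Synthetic world

The generator emulates the statistical structure the analysis assumes:

* Observed MDA8 is a seasonal sinusoid (mean 70 µg/m³, amplitude 25,
  mid-July peak, daily noise sd 12, truncated at zero), so cities exceed
  the 70 µg/m³ threshold on a realistic fraction of days.  Deaths are
  Poisson with a log-linear winter-peaking baseline (30/day per city); a
  known ozone effect on deaths can be injected for recovery experiments.
* Model fields place each city's true series (plus an injected bias:
  none / shift / scale / month-dependent / quantile-dependent; default a
  +4 µg/m³ shift, matching the magnitude of typical raw-model
  overestimates) on a 2° regular grid and up-sample to hourly with a fixed
  half-sine diurnal shape that is zero at night and scaled so the daily
  MDA8 of the hourly series equals the daily target exactly — MDA8
  extraction is exactly invertible, which is what makes the 1e−9
  end-to-end tolerances meaningful.
* Future fields add a per-scenario mean trend (defaults −8, +1, +9,
  +4 µg/m³ for SSP1-2.6/2-4.5/3-7.0/5-8.5); anomalies and ensemble-member
  noise are keyed by day-of-period rather than by calendar period, so a
  zero-trend, zero-bias world is exactly period-symmetric — the
  conservation property several tests rely on.
* Demographic factors anchor the present period at (1, 1) and default to
  future (ΔY_b, ΔPOP) of (1.30, 1.10), (1.40, 1.15), (1.50, 0.95),
  (1.35, 1.10) per scenario — ageing-driven rate increases with
  scenario-dependent population change — with a 10% lognormal per-country
  jitter.  Exposure-response RRs are uniform in [1.0008, 1.0035] per
  10 µg/m³ with se(β) = 0.25·β.
* The default world uses 20 cities in 5 countries, five models with one
  member each, 2010–2014 and 2050–2054 windows and a 2012–2014 training
  window.  City/country counts are desk-scale; the grid is a regular
  mid-latitude box.  These sizes keep the full default pipeline run in the
  tens of seconds while preserving every structural feature of the method.

What passing tests therefore show: the numerics of every stage are correct
against independent oracles, the bias correction is exactly calibrated on
its training distribution, and the pipeline conserves burden in the
identity world.  What they do not show: skill on real chemistry-climate
output (no spatial covariance, no synoptic weather, no model drift or
non-stationary biases), realism of any particular city's burden, or the
validity of the stationarity and threshold assumptions themselves.

## Numerical and degenerate-input behaviour

Quantiles use the standard linear-interpolation empirical definition
throughout.  All-missing days are omitted with a warning; months absent
from a fitted map raise on application; empty series, zero denominators,
unordered intervals and non-positive factors raise typed errors.  All
randomness derives from one root seed through labelled substreams
(CRC32-keyed `SeedSequence`), so every artifact regenerates
byte-identically and partial re-runs do not perturb one another.
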