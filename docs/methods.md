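# Methods

This document describes the scientific content of the package: the model
equations, their parameters and defaults, the rules used to turn growth
measurements into bud-break dates, the calibration and trend-estimation
procedures, the synthetic-data generators, and the numerical and design
choices that shape the implementation.

## 1. Rate functions

**Forcing.** Daily mean air temperature `T` (°C) contributes forcing units
(FU) at the rate

```
R_f(T) = 0                          for T ≤ 0
R_f(T) = a / (1 + exp(−b (T − c)))  for T > 0
```

Defaults: `a = 28.361` FU/day (asymptote), `b = 0.185` °C⁻¹ (steepness),
`c = 18.431` °C (inflection temperature). Bud break is predicted on the
first day the cumulative forcing sum reaches the critical value
`F* = fu_crit` (default 50 FU). The cut at 0 °C makes the function
discontinuous there; this is intentional — sub-zero days contribute
nothing.

**Chilling.** Chilling units (CU) accumulate at the triangular rate

```
R_c(T) = 0                  for T ≤ −3.4 or T > 10.4
R_c(T) = 0.159 T + 0.506    for −3.4 < T ≤ 3.5
R_c(T) = −0.159 T + 1.621   for 3.5 < T ≤ 10.4
```

clamped at zero from below. The clamp matters only in a narrow band just
above −3.4 °C, where the printed rising-branch coefficients dip slightly
negative (−0.035 at the breakpoint); we treat that as a rounding artifact
of the published coefficients rather than a real negative chilling effect.
The peak rate is 1.0625 CU/day at 3.5 °C.

## 2. Model structures

Both structures predict, for a labelled spring, the first day on which
cumulative forcing reaches `F*`. The prediction window closes on June 30;
if the requirement is not met by then, the prediction is `None`
("not reached") rather than an extrapolated date.

**Chilling model (`IA`).** Rest begins on a fixed calendar day of the
*previous* year (default September 1). Chilling accumulates daily;
competence (rest release) is assessed at the end of each day, and forcing
accumulation starts on the *following* day. Default chilling requirement
`C* = cu_crit = 20` CU. Special case: with `C* = 0` competence holds
before any chilling day is consumed, so forcing starts on the rest-start
day itself. This makes `IA` with `C* = 0` structurally identical to the
fixed-date model whose start is the rest-start day — up to window
labelling, since the `IA` window for year `Y` opens in year `Y − 1`.

**Fixed-date model (`DL`).** Forcing accumulates from a fixed day of year
(default March 15, day 74), with no chilling sub-model. This is the
degenerate limit of the chilling model in which rest is assumed released
by the start date.

**Gap handling.** If the temperature record has a missing day anywhere in
the span of days the model actually consumes (for `IA`, from the previous
September 1), prediction raises a `GapError` naming the date. Gaps after
the predicted bud-break day are irrelevant and ignored.

## 3. From growth measurements to bud-break dates

Field observations are repeated per-tree measurements of cumulative
leader-shoot length (mm). A plot-year's bud-break date is derived as:

1. Interpolate each tree's measurements linearly onto a daily grid; a
   tree's season total is its last measurement.
2. Bud break is the first day on which **both** hold:
   - strictly more than 50 % of the plot's trees have at least 1 mm of
     growth, and
   - the plot-mean growth is at least 1 % of the plot-mean season total.

The mean-growth guard keeps a few precocious trees from defining the date;
the majority criterion keeps one laggard from delaying it. If the criteria
already hold on the first measurement day the date is flagged as
left-censored (the true date may be earlier). If they never hold, the
plot-year yields a `NoBudBreak` marker rather than a date.

## 4. Published reference data

`budbreak.datasets` ships the study constants: observed bud-break dates
for five plots (two at a northern site, three at a southern site) over
three seasons; fitted parameter sets and their in-sample RMSEs for both
model structures at both sites; mean April–May temperature offsets between
the observation sites and the long-record stations used for
reconstruction (−1.4 to +1.7 °C); the published century-scale trend
coefficients (−0.028 to −0.045 days/year over a 107-year horizon, i.e. a
3.0–4.8 day advance); and the calibration bounds in Table form
(`published_bounds`).

## 5. Genetic-algorithm calibration

The objective is the RMSE (days) between predicted and observed bud-break
dates over all plot-years; a prediction of `None` is penalized by scoring
it as June 30. The search is a generational GA over the model's free
parameters, each clipped to its published bound:

| Parameter | Bounds | Notes |
|---|---|---|
| `fu_crit` | [0, 250] FU | |
| `a` | [15, 40] FU/day | |
| `b` | [0.01, 1.0] °C⁻¹ | |
| `c` | [5, 30] °C | |
| `cu_crit` (`IA`) | [0, 120] CU | |
| `forcing_start_doy` (`DL`) | [1, 151] | integer gene, Jan 1 – May 31 |

Settings follow the original protocol where deterministic: population 250,
per-gene mutation rate 0.1, uniform crossover with probability 0.7,
tournament selection of size 3, one elite, Gaussian mutation with standard
deviation 10 % of each bound's width, convergence threshold 10⁻⁴ days. The
original wall-clock patience ("stop after 60 s without improvement") is
replaced by a deterministic patience of 50 generations without an
improvement larger than the threshold, capped at 500 generations. The
published default parameter vector is seeded into the initial population,
so the fitted model is never worse than the uncalibrated one, and elitism
makes the best-so-far RMSE non-increasing. Ties in RMSE are broken toward
smaller `fu_crit`, then smaller `cu_crit` (the more parsimonious
requirement).

## 6. Reconstruction and trend analysis

**Reconstruction.** A long station record is first shifted by the
site–station offset (a constant, estimated as the mean April–May daily
difference over shared years). For each year, the fitted model predicts a
bud-break day of year. A year is omitted when the record has any gap in
the April 1 – May 31 omission window, or when the model consumes a missing
day anywhere in its accumulation span; years whose forcing requirement is
not met by June 30 are flagged separately. Omission reasons are recorded
per year.

**Trend.** The reconstructed day of year is modelled as
`DOY_t = β₀ + β₁·year_t + ε_t` with AR(p) errors. The maximum-likelihood
fit uses a state-space ARIMA(p, 0, 0) with the (centred) year as an
exogenous regressor, which handles omitted years as missing values; an
ordinary-least-squares fit is reported alongside for comparison (its
standard errors ignore serial correlation and are anti-conservative when
residuals are positively autocorrelated). `ar_order="auto"` selects
p ∈ {0, 1, 2} by AIC. Residual autocorrelation is summarized by the
Durbin–Watson statistic and the lag-1 autocorrelation with a permutation
p-value (999 permutations, seeded). The slope times the horizon (default
107 years) gives the implied total change in days.

Simulation checks (see `tests/test_acceptance.py` and
`scripts/acceptance.py`) show the ML slope estimator is unbiased under
AR(1) noise and that its 5 %-level test of a true null rejects at close to
the nominal rate.

## 7. Synthetic data generators

**Climate.** Daily temperature is a seasonal mean
`mean + amplitude·cos(2π(doy − phase)/365.25)` plus a linear trend
(°C/decade) plus an AR(1) anomaly. The anomaly's `sd` parameter is its
*marginal* standard deviation (innovation sd = `sd·√(1 − φ²)`), started
from the stationary distribution. The subarctic preset (mean −1 °C,
amplitude 14 °C, phase day 200, φ = 0.6, sd 3 °C) gives winters around
−15 °C and summers around 13 °C. Requested gap intervals are blanked to
NaN. The generator is a study condition: its defaults are not tuned to any
downstream test.

**Observations.** For each plot-year the true model gives a bud-break
date; each tree's onset is jittered by a uniform integer within ±2 days
(default). A tree's cumulative growth is zero before onset, jumps at onset
to just above the detection criteria (1.02 × max(1 mm, 1 % of the
plot-scale season total)) and then saturates toward the tree's season
total (drawn from a normal distribution, mean 120 mm, sd 30 mm) as
`1 − exp(−3t/40)`. Gaussian measurement noise is added and the series is
passed through a running maximum, because cumulative length cannot
decrease. The onset jump guarantees the exact-recovery property: with zero
noise, zero jitter and daily sampling, the derived date equals the true
date.

With the default ±2-day tree jitter, the derived plot date tracks an order
statistic of the jittered onsets, which puts an irreducible floor of
roughly a day under the recovery error even with daily sampling; weekly
sampling adds bracketing error of up to the measurement interval. The
end-to-end tests assert recovery at that honest resolution (daily median
RMSE ≤ 1.2 days, weekly ≤ 3.0 days, daily strictly better than weekly).

## 8. Numerical choices

- Predictions use vectorized cumulative sums over the consumed window with
  explicit first-gap checks; an independent pure-Python day-loop oracle in
  the test suite (`tests/oracles.py`) verifies equivalence on random
  series and models for both structures.
- Trend fitting delegates to `statsmodels` (state-space ARIMA, OLS,
  Durbin–Watson); the permutation test for lag-1 autocorrelation is
  implemented here because no installed package provides that exact test.
- The pipeline writes byte-deterministic artifacts: no timestamps, a
  manifest with the SHA-256 of the canonicalized config and of each
  artifact; stage timings are reported to the log only.
- Temperatures outside [−60, 45] °C are rejected at ingestion as sensor or
  transcription errors.

## 9. Limitations

- The forcing and chilling responses are fixed functional forms; the
  package calibrates their parameters but does not compare alternative
  response shapes.
- The station offset is a single additive constant estimated from spring
  months; any seasonality or long-term drift in the site–station
  difference is not modelled.
- The trend model is linear with AR(p) errors; breakpoints or nonlinear
  climate responses are out of scope (a robust Theil–Sen slope is easy to
  compute on the reconstructed series if a check is wanted).
- The synthetic growth curve is phenomenological. It reproduces the
  detection geometry around onset, not shoot physiology, and is intended
  for validating the observation-derivation and calibration machinery.
- Predictions use daily mean temperature only; diurnal structure beyond
  the daily mean (available via the hourly aggregation path) is not used
  by the models themselves.
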