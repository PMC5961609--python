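# Methods

This note documents the models, conventions and design choices behind the
package, and what its synthetic-data tests do and do not establish about
real logger data.

## The exposure model

The unit of analysis is the dwelling. Input is a panel of temperature
readings at a nominal 20-minute cadence for up to three rooms (bedroom,
living room, hallway) per dwelling over a winter window — by default
February 2011, December 2011 and January 2012, the three ONS winter months
with monitoring coverage in the emulated survey. Timestamps are naive local
time; the winter window contains no DST transition, so no timezone handling
is implemented.

### Low-extreme correction

Per dwelling × room, the Tukey lower fence Q₁ − m·IQR (default m = 1.5) is
computed once on the combined readings of all window months, and readings
strictly below the fence are removed. Rationale: multi-day lows are the
signature of an unoccupied home, and the exposure of interest is the
occupied thermal state. Conventions:

- Quartiles use linear interpolation between order statistics (the common
  "type 7" rule); the convention is configurable since different software
  defaults differ slightly.
- Strictly-below removal: a reading exactly at the fence is kept.
- The fence is applied per room by default; a pooled per-dwelling fence
  over all three rooms is available (`preprocess_panel(pool_rooms=True)`)
  since survey descriptions of this step are ambiguous between the two.
- The operation is **not idempotent**: re-running it recomputes quartiles on
  the reduced sample and can remove more points. It is intended to run once.
- Series with fewer than 4 readings pass through unchanged (quartiles are
  not meaningful); they are flagged with a warning.

### Derived metrics

All threshold comparisons are inclusive ("at 18 °C or above"), including the
day-fraction boundary: a day with exactly 68 of 72 readings at the threshold
meets the criterion. The day fraction is stored as the exact ratio 68/72 and
compared with a 1e-12 float guard so the boundary case is never lost to
rounding.

- **Day eligibility.** A day enters the %-of-days denominator only with at
  least `min_readings_per_day` readings (default 36, i.e. 50% coverage).
  This prevents a nearly-empty day from counting as "meeting". The choice is
  a free parameter; results at full coverage are insensitive to it.
- **Segments.** A segment is a pair of consecutive readings exactly one
  cadence apart (±1 minute tolerance). Gaps break segments; no
  interpolation. This is the conservative reading of "consecutive
  measurements both at least 18 °C".
- **Day attribution.** Days run midnight to midnight; the segment ending at
  the next midnight belongs to the earlier day, so a fully-covered warm day
  contributes 72 segments = 24 h.
- **Terminal days.** The final monitored day of each month block has no
  subsequent day to close its cross-midnight segment. The default policy
  (`terminal_day_policy="exclude_day"`) excludes that whole day from the
  hour metrics (c)/(d); `"keep_day"` retains it with whatever segments it
  has. The day-criterion metric (b) is unaffected by the policy.
- **Nights.** Night *n* is the window 20:00 on day *n* to 08:00 on day
  *n*+1 (12 h, i.e. at most 36 segments). A segment counts when it lies
  entirely inside the window; the reading at exactly 08:00 closes the last
  segment of the night. Only the bedroom is summarised, on the assumption
  that is where occupants sleep.

### Statistical procedures

- **Repeated-measures ANOVA** (one within factor, the room) for mean winter
  temperatures, df = (k−1, (k−1)(n−1)); dwellings missing any room are
  dropped. No sphericity correction is applied by default — the integer-df
  convention used in the emulated analysis — and the statsmodels `AnovaRM`
  implementation is cross-checked in the tests against a hand
  sums-of-squares partition and against F = t² for the two-level case.
  Pairwise room contrasts are paired t tests, Bonferroni-adjusted over the
  three comparisons; their CIs use the adjusted level 1 − α/3.
- **Two-way factorial ANOVA** with LTD × over-64 and interaction, fitted as
  a Gaussian linear model. Type II sums of squares are the default for the
  unbalanced design (Type III available); with two binary factors and
  interaction the error df is n − 4 (631 at n = 635). The reported group
  contrast is the marginal (cell-mean-averaged) True−False difference with
  its t-based CI. An outcome with (numerically) zero variance yields F = 0,
  p = 1 for every effect rather than 0/0 noise.
- **Rank-transform ANOVA** for the non-normal metrics: midranks over the
  entire sample (ties averaged, rank 1 = lowest), then the factorial ANOVA
  on the ranks. This is implemented literally as the composition of the two
  steps, and a test asserts the exact identity against independently
  computed midranks. Group summaries are mean ranks; the difference CI is
  the two-way-ANOVA-on-ranks contrast interval — the exact variance
  estimator behind published rank-difference intervals of this style is not
  standardised, so the model-based interval is reported and labelled as
  such. The interaction test under rank transformation has inflated type-I
  error; its result carries a caution note (a *null* interaction remains
  informative). Null simulations in the acceptance suite confirm the main
  effects are calibrated (rejection rate 0.05 ± 0.01 at n = 200).
- **Relative risk** for "≥ 18 °C on ≥ 90% of days": RR = p₁/p₀ with the
  standard log-normal CI, exp(ln RR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d))),
  no continuity correction. Zero outcome cells leave the CI undefined
  rather than silently corrected.
- **Kernel densities** use a Gaussian kernel with the normal-reference
  (Silverman) bandwidth; the default grid extends 4 bandwidths beyond the
  data range so the trapezoid integral is 1 within 10⁻³. Degenerate
  (zero-variance or n < 2) inputs raise.

## The synthetic-data generator

Per reading: T = B(d) + offset(room) + day(d, date) + H(room, clock) + ε,
quantised to the 0.01 °C sensor resolution, where

- B(d) ~ Normal(`base_mean_c` = 18.5, `between_home_sd_c` = 2.5) plus
  additive shifts `ltd_effect_c` and `age_effect_c` (default 0.5 °C each —
  the order of the group differences observed in English winter monitoring)
  for households drawn Bernoulli at the survey prevalences (369/635 LTD,
  206/635 over-64);
- day(d, date) ~ Normal(0, `day_sd_c` = 1.2), one draw per dwelling-day
  shared across rooms — the weather-driven day-to-day component. No survey
  value for this SD is published; it is a free parameter chosen so that
  day-level criterion metrics spread over (0, 100)% rather than collapsing
  to the extremes, and it is the main dial for how intermittent the
  exposure is;
- H is the heating-schedule component (default on-windows 06:30–09:00 and
  16:00–22:30 in every room, amplitude 1.5 °C), mean-centred so the winter
  mean of a home is B + offset in expectation; the living room sits
  +0.7 °C above bedroom and hallway, reproducing the observed room
  ordering;
- ε ~ Normal(0, `noise_sd_c` = 0.8) iid per reading;
- absence episodes arrive Poisson (`absence_rate` = 0.3 per
  dwelling-month), start uniformly, last 1–3 days, and subtract
  `absence_drop_c` = 6 °C in **all** rooms — these produce the low tail the
  fence correction removes;
- whole dwelling×room days are lost with probability
  `missing_day_rate` = 0.03.

Identical (config, seed) produces bit-identical output; household and
series generation use separate child streams of the seed so each is
reproducible on its own. `simulate_winter_means` draws per-dwelling winter
means directly from the same model marginalised over time (the centred
heating term averages out; noise and day effects shrink by √n); it exists
for Monte-Carlo studies of the group statistics where full panels would add
nothing but runtime.

**What the generator does not emulate:** correlation between LTD and age
(drawn independently), heterogeneous heating schedules, external-weather
trends shared *between* homes, sensor drift, occupancy feedback on heating,
and any dependence of missingness on temperature. Passing synthetic-recovery
tests therefore shows the pipeline's correctness and calibration under the
stated model, not that real English homes have these parameter values.

## Problem sizes used in checks

The acceptance script simulates the full study scale (635 dwellings, three
rooms, three months at 20-minute cadence ≈ 12 million readings). The
Monte-Carlo calibration studies use 500 replicates (CI coverage of a planted
0.5 °C effect at n = 635) and 1 000 replicates (type-I error at n = 200) on
the dwelling-level fast path; unit and property tests use panels of 2–8
dwellings over one month.

## Known limitations

- The fence correction cannot distinguish genuinely cold occupied spells
  from absence; like any one-sided outlier rule it may retain empty-home
  days (biasing criterion metrics down) or remove real cold snaps.
- Rank-difference CIs are model-based (see above) and not directly
  comparable to intervals produced by other variance estimators.
- The relative-risk CI uses the large-sample log-normal approximation; it
  is unreliable with very small outcome counts.
- The pipeline treats rooms as fixed labels; homes monitored in fewer than
  three rooms simply yield NaN for the missing rooms and are dropped from
  the repeated-measures contrast.
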