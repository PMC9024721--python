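# Methods

This note documents the model assumptions, parameter choices and numerical
conventions behind `biogasmpc`, and what the synthetic test bed does and
does not establish about real plants.

## Controller model

The controller treats the digester as a linear time-invariant system from
hourly solid-feed mass to hourly gas volume, identified online:

    Y_t = α + β₀X_t + β₁X_{t−1} + … + β_kX_{t−k} + ε_t

* **Lag order `k`** (default 24 h, configurable). The solid substrates of
  interest (manure/corn/grass silage mixes) release most of their gas
  within a day of feeding; k = 24 covers those kinetics while leaving a
  500-row OLS problem with 26 parameters comfortably over-determined.
* **Estimation** is ordinary least squares on the rolling window of the
  last 500 h (≈3 weeks); the first k rows are dropped for lack of lags.
  No regularisation by default — the binary-ish feeding patterns produced
  by the sampler keep the lag columns well conditioned. A ridge option
  (`ridge > 0`, intercept unpenalised) exists for collinear feed logs.
  Degenerate designs fail loudly: constant feed raises an error naming the
  zero-variance regressor; a window shorter than `2k + 3` hours is
  rejected as unidentifiable.
* **The intercept α** absorbs all production the feed regressors cannot
  explain — residual degradation of older substrate and the daily liquid
  manure co-feeding, which is deliberately not a regressor (its specific
  yield is low and logging it is not universally available). The
  consequence, reproduced by the closed loop, is that the simulation floor
  is α: after a demand halving the model must wait for low-production
  hours to enter the 500-h window before it can simulate low output, so
  demand decreases track worse than increases.
* **Simulation** evaluates the fitted equation with ε_t = 0, seeded with
  the k observed pre-horizon feed lags; negative predictions (possible
  with a negative fitted α or β) are clipped to 0 with a warning.

## Demand conversion and planning

Power-to-biogas conversion uses fixed plant constants: CHP electrical
efficiency 0.35, 5.5 kWh per m³ raw biogas (~60 % CH₄), two digesters and
a scaling factor f_s. The division by the digester count applies to the
whole expression — demand is planned per digester. f_s may vary per hour
within a horizon, which matters on the evening before a phase change: the
48-h plan already sees tomorrow's halved (or restored) demand.

Candidate timetables are drawn cell-wise Bernoulli on the 576-cell 5-min
grid. The POS calibration makes the *expected* total feed mass of a
candidate equal the horizon's demand divided by the historical specific
yield; the pool's binomial spread (±3 SD ≈ ±9 events around a mean of
~18 per 48 h at full demand) is what gives the selector room to shape
production within the day. Conventions:

* POS > 1 (infeasible demand) is clipped to 1 with a warning — a Bernoulli
  parameter must be a probability, and the 12-cell hour already caps feed
  at 6000 kg/h.
* The blackout window is applied by zeroing cells *after* sampling; POS is
  not re-inflated to compensate. The window defaults to the three hours
  immediately after the planning instant (midnight), matching its
  practical purpose (schedule transfer, feeder refill before the day's
  feedings).
* Selection minimises the mean symmetric ratio |D−z|/(D+z) over the 48-h
  horizon. Hours with D + z = 0 contribute 0. Ties (e.g. the degenerate
  zero-demand case, where every empty candidate scores 1) are broken by
  the lowest candidate index, so runs are bit-reproducible under a seed.
* Receding horizon: only the first 24 h of the selected plan execute; the
  rest exists so today's feeding accounts for tomorrow's demand.

## The synthetic plant

The virtual digester is intentionally the *matched* case for the
controller: gas output is a lagged linear response

    gas_t = baseline + Σ_j g_j · feed_{t−j} + manure response + noise

with a discretised first-order-decay kernel g_j ∝ e^(−j/τ), τ = 8 h over
24 h, scaled to a total specific yield of 0.8 m³ per kg fresh mass;
baseline 20 m³/h; Gaussian measurement noise (sd 3 m³/h) clipped at zero.
The unmodelled disturbance is one daily 6000-kg liquid-manure bolus
(default 10:00) through a faster kernel (τ = 3 h over 12 h) with a low
specific yield of 0.025 m³/kg — realistic for liquid cattle manure and
enough to visibly perturb the hours after the bolus.

The demand generator tiles 24-h weekday and weekend (×0.78) mean profiles
with additive Gaussian noise (sd 6 kWh, ~6 % of the mean). The default
weekday profile was calibrated once against four site statistics at full
demand (f_s = 4): weekly-mean biogas demand ≈ 107 m³/h, full-demand
extremes ≈ 40–170 m³/h, and a largest within-day spread near 95–100 m³.
The four-phase schedule (15/9/7/5 days at f_s = 4/2/4/2) alternately
halves and restores demand. Phase scaling is applied at conversion time,
not in the generator, so the generated series is the raw site profile.

Warm-up: before day 1 the digester runs 28 days (≥ 500 h of feed/gas
history, 4 weeks of demand history) fed by a plant-side generator that
places roughly the demand-covering number of 500-kg events at random
non-blackout hours each day. This uses the plant's true kinetics — it is
scaffolding for a plausible operating history, not controller knowledge.

**What the matched plant does and does not show.** Because the plant is
lag-linear, the controller's model class contains the truth; closed-loop
error then isolates the contributions of the Monte-Carlo pool's tracking
granularity, the unmodelled manure disturbance, measurement noise and the
rolling-window adaptation lag. It does not probe model-class mismatch
(nonlinear inhibition, substrate changes, temperature effects), actuator
faults beyond the optional random feeding-failure injection, or forecast
model quality (the seasonal-naive default simply replays last week,
noise included). Real-plant error budgets will differ accordingly.

## Numerical and reporting conventions

* All series are gap-free hourly pandas series; validation names the first
  missing or offending timestamp.
* SMAPE_Q is reported in percent and equals 100× the selection score;
  MAPE refuses zero actual values rather than skipping them silently
  (use SMAPE when a series can touch zero). Each evaluated day aggregates
  exactly 24 hourly observations; days are calendar days at plan time.
  The signed daily difference is Σ(produced − demand); positive =
  overproduction. Phase boundaries come from the scenario config, never
  from the data.
* The organic loading rate is daily fresh mass × oDM fraction / reactor
  volume (kg oDM m⁻³ d⁻¹), an evaluation statistic only.
* Randomness: a run's integer seed feeds a `SeedSequence` that spawns
  independent generators for demand noise, plant noise, warm-up placement,
  feeding failures and the daily samplers, so sub-systems can be varied
  without perturbing each other.

## Problem sizes

The default experiment — 36 daily cycles × 1500 candidates × 48-h
simulation with k = 24, plus a 28-day warm-up — runs in a few seconds on
one CPU; the acceptance script and the full test suite (including three
complete closed-loop runs and 200-replicate coverage checks) each finish
in well under a minute.

## Known limitations

* The seasonal-naive forecaster propagates last week's noise into the
  demand target; a smoothing forecaster (the contract accepts any
  callable) would lower the apparent closed-loop MAPE by a point or two.
* With 500-kg increments a single feeding adds ~41 m³ in its first hour —
  large relative to halved-demand nights (~35–55 m³/h) — so low-demand
  phases have an intrinsic quantisation floor in MAPE that smaller
  increments would reduce.
* POS is not re-normalised for the blackout window (a ~6 % downward bias
  in expected feed mass), absorbed in practice by the selector picking
  from the pool's upper tail.
* The closed loop assumes the plant accepts the hourly aggregation of the
  5-min schedule; sub-hourly plant dynamics are not represented.
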