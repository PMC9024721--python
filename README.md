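# biogasmpc

Model-predictive feeding control for demand-orientated biogas production.

Biogas plants are one of the few renewable generators whose output can be
scheduled: the substrate in the feeder is a chemical energy store, and the
timing of solid feedings shapes the digester's gas production hours later.
`biogasmpc` implements a practical controller that aligns a full-scale
digester's raw-biogas output with a site's electricity demand using only
three routinely measured signals — metered power demand, the mass of solid
substrate fed, and the volumetric gas flow. No mechanistic digestion model
(ADM1-style) and no substrate characterisation are required.

It is aimed at researchers and engineers working on load-flexible anaerobic
digestion who want a testable, end-to-end reference controller, including a
synthetic full-scale plant so every stage runs without plant data.

## The controller

Once per day the controller plans 48 h ahead and executes 24 h (receding
horizon):

1. **Demand forecast.** Hourly power demand is forecast 48 h ahead from the
   last four weeks of history. The forecaster is a pluggable contract; the
   default is seasonal-naive (same hour, same weekday, previous week).
2. **Biogas demand.** The forecast is converted to raw-biogas demand
   (~60 % CH₄) per digester:

       D_t = P_t · f_s / (η_CHP · f_kWh/m³) / n

   with scaling factor `f_s` (4 = full demand, 2 = halved), CHP electrical
   efficiency `η_CHP` = 0.35, energy content 5.5 kWh per m³ raw biogas, and
   `n` = 2 digesters.
3. **Candidate timetables.** The 48-h horizon is a grid of 576 five-minute
   intervals; each cell is one possible 500-kg feeding. 1500 candidate
   timetables are drawn cell-wise Bernoulli with probability of success

       POS = ( ΣD_t / yield / 500 kg ) / 576 ,   yield = b̄_hist / s̄_hist

   where the specific biogas yield (m³/kg) comes from the last 500 h of
   observation. A daily 3-h blackout window (data transfer, feeder refill)
   is forced to zero. The 12-cell hour caps feeding at 6000 kg/h.
4. **Gas simulation.** A distributed-lag regression

       Y_t = α + β₀X_t + β₁X_{t−1} + … + β_kX_{t−k} + ε_t

   (default k = 24 h) is refit by OLS on the rolling 500-h window and
   evaluated for every candidate, including the pre-horizon feed lags.
5. **Selection.** The candidate minimising the symmetric mean absolute
   percentage error, mean |D_t − z_t| / (D_t + z_t), is executed.

The package also provides a **virtual plant** — a lag-linear digester with a
first-order-decay response kernel, an endogenous baseline, measurement
noise, and a daily 6000-kg liquid-manure bolus the controller deliberately
does not model — plus a site demand generator with day/night and
weekday/weekend cycles and a four-phase schedule that alternately halves
and restores demand (15/9/7/5 days at f_s = 4/2/4/2).

## Worked example

Generate a 28-day warm-start dataset, plan one day, and run the full
36-day closed-loop experiment:

```
$ biogasmpc fixtures --out fx --seed 1 --days 28
wrote 28-day warm-start dataset to fx

$ biogasmpc plan --power fx/power.csv --feed fx/feed.csv --gas fx/gas.csv \
      --seed 1 --out schedule.csv
selected candidate #437 (SMAPE 8.46 %, 11 feedings, POS 0.0179) -> schedule.csv

$ biogasmpc simulate --seed 1 --out run
36-day closed loop complete; mean daily demand-vs-production MAPE 19.9 %, \
mean OLR 0.66 kg oDM m-3 d-1 -> run
```

The `plan` line says: with a per-cell feeding probability of 0.0179 the
best of 1500 random timetables schedules eleven 500-kg feedings whose
simulated 48-h production deviates from the biogas demand by 8.46 %
(symmetric MAPE). The `simulate` run writes `hourly.csv` (demand,
simulated and produced gas, executed feed), `daily_report.csv` (per-day
SMAPE/MAPE/MAE and the signed demand-production balance for all three
comparisons), `phase_summary.csv` (mean ± SD per phase, e.g. phase-1
demand-vs-produced MAPE 17.7 ± 3.0 %) and a `manifest.json` that pins the
config hash and seed for bit-identical replay. The organic loading rate of
the solid feed (here 0.66 kg oDM m⁻³ d⁻¹ at a ~30 % oDM mix in an 850-m³
digester) is echoed as a process-stability context figure.

The same functionality is available as a library:

```python
from biogasmpc import LoopConfig, run_closed_loop

result = run_closed_loop(LoopConfig(seed=1))
print(result.mean_daily_mape())   # 19.91
```

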