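"""The daily planning cycle and the receding-horizon closed loop.

Each simulated day at midnight the controller

1. forecasts the site's power demand 48 h ahead and converts it to a
   biogas-demand series with the phase's scaling factor,
2. computes the historical specific yield and the per-cell feeding
   probability (POS) from the last 500 h of feed/gas observations,
3. draws 1500 candidate feeding timetables on the 5-min grid,
4. refits the distributed-lag gas model on the same 500-h window and
   simulates each candidate's 48-h production,
5. selects the candidate with the lowest symmetric mean absolute
   percentage error against the demand (ties: lowest candidate index),

then executes only the first 24 h of the selected plan on the plant,
appends the realised feed and gas to the histories, and re-plans the
next day with the window rolled forward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .demand import ConversionParams, forecast_power, power_to_biogas
from .gasmodel import (LagModel, TrainingWindow, fit_lag_model,
                       simulate_gas_batch)
from .plant import (DemandScenario, DigesterParams, VirtualDigester,
                    generate_demand, warm_start)
from .scheduler import (CELLS_PER_HOUR, FeedingTimetable, SchedulerConfig,
                        probability_of_success, sample_timetables,
                        specific_biogas_yield)

logger = logging.getLogger(__name__)

HOURS_PER_DAY = 24


def score_candidate(demand, simulated) -> float:
    """Mean symmetric ratio |D_t - z_t| / (D_t + z_t) over the horizon.

    Hours where demand and simulation are both zero contribute 0.
    Dimensionless in [0, 1]; equals SMAPE_Q / 100.
    """
    d = np.asarray(demand, dtype=float)
    z = np.asarray(simulated, dtype=float)
    if d.shape != z.shape or d.ndim != 1:
        raise ValueError(f"demand and simulation lengths differ: "
                         f"{d.shape} vs {z.shape}")
    denom = d + z
    ratio = np.where(denom > 0, np.abs(d - z) / np.where(denom > 0, denom, 1.0),
                     0.0)
    return float(ratio.mean())


def score_batch(demand: np.ndarray, simulated: np.ndarray) -> np.ndarray:
    """Vectorised :func:`score_candidate` over candidate rows."""
    d = np.asarray(demand, dtype=float)
    z = np.asarray(simulated, dtype=float)
    denom = d[None, :] + z
    ratio = np.where(denom > 0,
                     np.abs(d[None, :] - z) / np.where(denom > 0, denom, 1.0),
                     0.0)
    return ratio.mean(axis=1)


@dataclass
class PlanningResult:
    """Outcome of one daily planning cycle."""

    selected: FeedingTimetable
    selected_index: int
    selected_smape: float
    simulated_gas: np.ndarray        # selected candidate, m^3/h over horizon
    candidate_scores: np.ndarray
    demand: pd.Series
    pos: float
    specific_yield: float
    model: LagModel


def plan_day(feed_hist, gas_hist, demand48: pd.Series,
             cfg: SchedulerConfig | None = None, *, k: int = 24,
             train_window_h: int = 500,
             rng: np.random.Generator | None = None,
             extra_candidates: list[FeedingTimetable] | None = None,
             ) -> PlanningResult:
    """One planning cycle: calibrate, sample, simulate, select.

    ``feed_hist`` and ``gas_hist`` must cover at least ``train_window_h``
    hours up to the planning instant.  ``extra_candidates`` are appended
    to the Monte-Carlo pool (used for injection tests and replay).
    Fully reproducible for a given ``rng``.
    """
    cfg = cfg if cfg is not None else SchedulerConfig()
    feed = np.asarray(feed_hist, dtype=float)
    gas = np.asarray(gas_hist, dtype=float)
    demand_vals = np.asarray(demand48, dtype=float)
    if demand_vals.size != cfg.horizon_h:
        raise ValueError(f"demand covers {demand_vals.size} h but the horizon "
                         f"is {cfg.horizon_h} h")

    spec_yield = specific_biogas_yield(gas, feed, train_window_h)
    pos = probability_of_success(float(demand_vals.sum()), spec_yield,
                                 cfg.increment_kg, cfg.n_cells)
    candidates = sample_timetables(pos, cfg, rng=rng)
    if extra_candidates:
        candidates = candidates + list(extra_candidates)

    window = TrainingWindow(feed[-train_window_h:], gas[-train_window_h:])
    model = fit_lag_model(window, k=k)
    hourly = np.stack([c.hourly_kg for c in candidates])
    sims = simulate_gas_batch(model, feed[-k:] if k else feed[:0], hourly)
    scores = score_batch(demand_vals, sims)
    best = int(np.argmin(scores))  # first minimum -> lowest index on ties
    logger.info("plan: POS=%.4f yield=%.3f m3/kg scores q25/50/75="
                "%.3f/%.3f/%.3f selected=%.4f (#%d, %d feedings)",
                pos, spec_yield, *np.percentile(scores, (25, 50, 75)),
                scores[best], best, candidates[best].n_feedings)
    return PlanningResult(selected=candidates[best], selected_index=best,
                          selected_smape=float(scores[best]),
                          simulated_gas=sims[best], candidate_scores=scores,
                          demand=demand48, pos=pos, specific_yield=spec_yield,
                          model=model)


@dataclass
class LoopConfig:
    """Everything a closed-loop run needs; defaults are the study settings."""

    conversion: ConversionParams = field(default_factory=ConversionParams)
    scheduler: SchedulerConfig = field(default_factory=SchedulerConfig)
    scenario: DemandScenario = field(default_factory=DemandScenario)
    digester: DigesterParams = field(default_factory=DigesterParams)
    k: int = 24
    train_window_h: int = 500
    warmup_days: int = 28
    #: fraction of planned feeding events silently skipped at execution
    feeding_failure_rate: float = 0.0
    start: str = "2022-01-03"  # a Monday; warm-up precedes it by 4 weeks
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.feeding_failure_rate <= 1.0:
            raise ValueError("feeding_failure_rate must be in [0, 1]")
        min_days = max(self.train_window_h / HOURS_PER_DAY, 28)
        if self.warmup_days < min_days:
            raise ValueError(f"warm-up must cover the {self.train_window_h}-h "
                             f"training window and 4 weeks of demand history "
                             f"(>= {int(np.ceil(min_days))} days)")


@dataclass
class DayRecord:
    """One executed day of the closed loop."""

    day: int                     # 1-based experiment day
    scaling_factor: float
    demand: pd.Series            # 24 h actually targeted
    executed_kg: np.ndarray      # 24 h realised feed
    produced: np.ndarray         # 24 h plant gas output
    simulated: np.ndarray        # first 24 h of the selected simulation
    plan: PlanningResult


@dataclass
class ClosedLoopResult:
    """Trajectory of a closed-loop run."""

    days: list[DayRecord]
    hourly: pd.DataFrame         # demand, simulated, produced, feed_kg
    config: LoopConfig

    def daily_metrics(self) -> pd.DataFrame:
        from .evaluation import daily_report
        return daily_report(self.hourly[["demand", "simulated", "produced"]])

    def mean_daily_mape(self, comparison: str = "demand_vs_produced") -> float:
        daily = self.daily_metrics()
        sel = daily[daily["comparison"] == comparison]
        return float(sel["mape_pct"].mean())


def run_closed_loop(config: LoopConfig | None = None, days: int | None = None,
                    seed: int | None = None) -> ClosedLoopResult:
    """Run the full receding-horizon experiment against the virtual plant.

    Generates the demand scenario, warms the digester up for
    ``config.warmup_days`` (building >= 500 h of self-consistent feed/gas
    history and 4 weeks of demand history), then executes one planning
    cycle per day: forecast, convert with the day's phase factors, plan,
    execute the first 24 h, roll the training window forward.
    """
    config = config if config is not None else LoopConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    n_days = config.scenario.n_days if days is None else int(days)
    warm = config.warmup_days
    if warm * HOURS_PER_DAY < config.train_window_h:
        raise ValueError("scenario shorter than warm-up requirements")

    ss = np.random.SeedSequence(config.seed)
    (demand_seed, plant_seed, warm_seed,
     fail_seed, plan_seed) = [np.random.default_rng(s) for s in ss.spawn(5)]

    # raw site demand over warm-up + experiment + the trailing lookahead day
    start = pd.Timestamp(config.start) - pd.Timedelta(days=warm)
    power = generate_demand(config.scenario, warm + n_days + 2,
                            seed=demand_seed, start=start)
    first_factor = config.scenario.phases[0][1]

    digester = VirtualDigester(config.digester, seed=plant_seed,
                               start_hour_of_day=0)
    blackout = (config.scheduler.blackout_start_hour,
                config.scheduler.blackout_duration_h)
    feed_hist, gas_hist = warm_start(
        digester, power.iloc[: warm * HOURS_PER_DAY], config.conversion,
        scaling_factor=first_factor,
        increment_kg=config.scheduler.increment_kg,
        blackout=blackout, seed=warm_seed)
    feed_vals = feed_hist.to_numpy().tolist()
    gas_vals = gas_hist.to_numpy().tolist()

    records: list[DayRecord] = []
    cells_per_day = HOURS_PER_DAY * CELLS_PER_HOUR
    for d in range(n_days):
        t0 = (warm + d) * HOURS_PER_DAY      # planning instant, hours
        history = power.iloc[t0 - 672: t0]
        fcst = forecast_power(history, config.scheduler.horizon_h)
        exp_hours = np.arange(d * HOURS_PER_DAY,
                              d * HOURS_PER_DAY + config.scheduler.horizon_h)
        factors = config.scenario.scaling_factors(exp_hours)
        demand48 = power_to_biogas(fcst, config.conversion,
                                   scaling_factor=factors)

        plan = plan_day(np.asarray(feed_vals), np.asarray(gas_vals), demand48,
                        config.scheduler, k=config.k,
                        train_window_h=config.train_window_h, rng=plan_seed)

        # receding horizon: execute only the first 24 h of the selected plan
        executed_grid = plan.selected.grid[:cells_per_day].copy()
        if config.feeding_failure_rate > 0:
            keep = fail_seed.random(cells_per_day) >= config.feeding_failure_rate
            executed_grid = executed_grid * keep
        executed_kg = (executed_grid.reshape(-1, CELLS_PER_HOUR).sum(axis=1)
                       * config.scheduler.increment_kg).astype(float)
        produced = digester.run(executed_kg)
        feed_vals.extend(executed_kg)
        gas_vals.extend(produced)

        records.append(DayRecord(
            day=d + 1, scaling_factor=float(factors[0]),
            demand=demand48.iloc[:HOURS_PER_DAY],
            executed_kg=executed_kg, produced=produced,
            simulated=plan.simulated_gas[:HOURS_PER_DAY], plan=plan))

    index = pd.date_range(config.start, periods=n_days * HOURS_PER_DAY,
                          freq="h")
    hourly = pd.DataFrame({
        "demand": np.concatenate([r.demand.to_numpy() for r in records]),
        "simulated": np.concatenate([r.simulated for r in records]),
        "produced": np.concatenate([r.produced for r in records]),
        "feed_kg": np.concatenate([r.executed_kg for r in records]),
    }, index=index)
    return ClosedLoopResult(days=records, hourly=hourly, config=config)
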