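"""Monte-Carlo construction of candidate feeding timetables.

A feeding timetable is a binary grid over the planning horizon at 5-min
resolution (576 cells for 48 h); each 1-cell is one feeding event of a
fixed substrate increment (default 500 kg).  Candidate timetables are
drawn cell-wise Bernoulli with a "probability of success" (POS)
calibrated so that the expected total feed mass covers the total biogas
demand of the horizon given the digester's historical specific yield:

    yield = mean(gas, last 500 h) / mean(feed, last 500 h)      [m^3/kg]
    POS   = (sum(D_t) / yield / s_fixed) / 576

Cells inside the daily blackout window (reserved at the plant for data
transfer and refilling the solids feeder) are forced to zero after
sampling.  The hourly aggregation of a grid is what the plant executes;
with 500-kg increments the 12-cell hour implicitly caps the feed rate at
6000 kg/h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CELLS_PER_HOUR = 12  # 5-min intervals


@dataclass
class FeedingTimetable:
    """Binary 5-min feeding grid plus its hourly mass aggregation."""

    grid: np.ndarray
    increment_kg: float = 500.0
    start: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 1 or grid.size % CELLS_PER_HOUR != 0:
            raise ValueError("grid must be 1-D with a whole number of hours "
                             f"(multiple of {CELLS_PER_HOUR} cells)")
        if not np.isin(grid, (0, 1)).all():
            raise ValueError("grid cells must be 0 or 1")
        if self.increment_kg <= 0:
            raise ValueError("increment_kg must be positive")
        self.grid = grid.astype(np.int8)

    @property
    def horizon_h(self) -> int:
        return self.grid.size // CELLS_PER_HOUR

    @property
    def n_feedings(self) -> int:
        return int(self.grid.sum())

    @property
    def hourly_kg(self) -> np.ndarray:
        """Mass fed per hour (kg): sum of each hour's 12 cells x increment."""
        return self.grid.reshape(-1, CELLS_PER_HOUR).sum(axis=1) * self.increment_kg

    def hourly_series(self) -> pd.Series:
        if self.start is None:
            raise ValueError("timetable has no start timestamp")
        index = pd.date_range(self.start, periods=self.horizon_h, freq="h")
        return pd.Series(self.hourly_kg, index=index, name="feed_kg")


@dataclass
class SchedulerConfig:
    """Monte-Carlo sampler settings (defaults are the plant's constants)."""

    n_timetables: int = 1500
    increment_kg: float = 500.0
    horizon_h: int = 48
    #: daily clock window with feeding forbidden; starts at the planning
    #: instant (midnight) by default
    blackout_start_hour: int = 0
    blackout_duration_h: int = 3
    max_hourly_kg: float = 6000.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_timetables < 1:
            raise ValueError("n_timetables must be >= 1")
        if self.blackout_duration_h < 0:
            raise ValueError("blackout_duration_h must be >= 0")
        if self.horizon_h < 1:
            raise ValueError("horizon_h must be >= 1")
        if self.increment_kg <= 0:
            raise ValueError("increment_kg must be positive")
        if abs(self.max_hourly_kg / self.increment_kg
               - round(self.max_hourly_kg / self.increment_kg)) > 1e-9:
            raise ValueError("max_hourly_kg must be a multiple of increment_kg")

    @property
    def n_cells(self) -> int:
        return self.horizon_h * CELLS_PER_HOUR


def specific_biogas_yield(gas_hist: Sequence[float] | pd.Series,
                          feed_hist: Sequence[float] | pd.Series,
                          window_h: int = 500) -> float:
    """Historical specific biogas yield (m^3 per kg fresh mass).

    Mean gas production over the last ``window_h`` hours divided by mean
    substrate feeding over the same window.
    """
    gas = np.asarray(gas_hist, dtype=float)
    feed = np.asarray(feed_hist, dtype=float)
    if len(gas) < window_h or len(feed) < window_h:
        raise ValueError(f"need at least {window_h} h of gas and feed history; "
                         f"got {len(gas)} and {len(feed)}")
    mean_feed = feed[-window_h:].mean()
    if mean_feed <= 0:
        raise ValueError("mean substrate feed over the window is zero — "
                         "specific yield of an unfed digester is undefined")
    return float(gas[-window_h:].mean() / mean_feed)


def probability_of_success(total_demand_m3: float, yield_m3_per_kg: float,
                           increment_kg: float = 500.0,
                           n_intervals: int = 576) -> float:
    """Per-cell Bernoulli probability calibrated to the horizon's demand.

    ``(total_demand / yield / increment) / n_intervals``, clipped into
    [0, 1] (the expression exceeds 1 only when demand is infeasible for
    the grid, which the 12-cell hourly cap bounds anyway).
    """
    if yield_m3_per_kg <= 0:
        raise ValueError("yield must be positive")
    if increment_kg <= 0:
        raise ValueError("increment_kg must be positive")
    if total_demand_m3 < 0:
        raise ValueError("total demand must be >= 0")
    pos = total_demand_m3 / yield_m3_per_kg / increment_kg / n_intervals
    if pos > 1.0:
        logger.warning("POS %.3f exceeds 1; clipped (demand infeasible for "
                       "the feeding grid)", pos)
        pos = 1.0
    return float(pos)


def blackout_mask(horizon_h: int, start_hour: int, duration_h: int,
                  first_hour_of_day: int = 0) -> np.ndarray:
    """Boolean cell mask, True where feeding is forbidden.

    ``first_hour_of_day`` is the clock hour of the grid's first cell, so
    the daily window can be laid onto horizons not starting at midnight.
    """
    hours = (np.arange(horizon_h) + first_hour_of_day) % 24
    hour_blocked = (hours - start_hour) % 24 < duration_h
    return np.repeat(hour_blocked, CELLS_PER_HOUR)


def sample_timetables(pos: float, cfg: SchedulerConfig | None = None,
                      rng: np.random.Generator | None = None,
                      start: pd.Timestamp | None = None,
                      ) -> list[FeedingTimetable]:
    """Draw ``cfg.n_timetables`` independent candidate timetables.

    Each cell is an independent Bernoulli(pos) draw; blackout cells are
    then forced to zero (POS is not re-inflated for the blocked cells).
    Reproducible for a given ``rng`` or ``cfg.rng_seed``.
    """
    cfg = cfg if cfg is not None else SchedulerConfig()
    if not 0.0 <= pos <= 1.0:
        raise ValueError("pos must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    grids = (rng.random((cfg.n_timetables, cfg.n_cells)) < pos).astype(np.int8)
    if cfg.blackout_duration_h > 0:
        mask = blackout_mask(cfg.horizon_h, cfg.blackout_start_hour,
                             cfg.blackout_duration_h)
        grids[:, mask] = 0
    return [FeedingTimetable(g, cfg.increment_kg, start=start) for g in grids]
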