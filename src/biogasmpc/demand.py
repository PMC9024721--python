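"""Power-demand forecasting and conversion to raw-biogas demand.

The controller plans against a 48-h biogas-demand series derived from a
forecast of the site's electricity demand.  Forecasting is a pluggable
contract (history in, horizon out); the default is a seasonal-naive
forecaster that repeats the value observed at the same hour of the same
weekday one week earlier.  The conversion to raw biogas (approx. 60 %
methane) is

    D_t = P_t * f_s / (eta_CHP * f_kWh_m3) / n_digesters

with a dimensionless scaling factor ``f_s`` (used to scale the site to the
CHP unit and to switch demand phases), the electrical CHP efficiency
``eta_CHP``, the volumetric energy content of raw biogas ``f_kWh_m3``
(kWh per m^3) and the number of digesters sharing the load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOURS_PER_WEEK = 168
#: minimum history the default forecaster requires: four full weeks
MIN_HISTORY_H = 4 * HOURS_PER_WEEK

Forecaster = Callable[[pd.Series, int], np.ndarray]


def check_hourly_series(series: pd.Series, name: str = "series",
                        require_nonnegative: bool = True) -> pd.Series:
    """Validate the hourly-series contract shared by all time series here.

    Requires a DatetimeIndex that is strictly increasing, exactly
    hourly-spaced and gap-free; optionally requires non-negative values.
    Raises ``ValueError`` naming the first offending timestamp.
    """
    if not isinstance(series, pd.Series):
        raise TypeError(f"{name}: expected a pandas Series, got {type(series).__name__}")
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError(f"{name}: expected a DatetimeIndex")
    if len(series) == 0:
        raise ValueError(f"{name}: series is empty")
    diffs = series.index.to_series().diff().iloc[1:]
    bad = diffs[diffs != pd.Timedelta(hours=1)]
    if len(bad):
        if bad.iloc[0] > pd.Timedelta(hours=1):
            missing = bad.index[0] - bad.iloc[0] + pd.Timedelta(hours=1)
            raise ValueError(f"{name}: missing hour at {missing}")
        raise ValueError(f"{name}: timestamps must be strictly increasing and "
                         f"hourly-spaced; violation at {bad.index[0]}")
    values = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name}: non-finite values present")
    if require_nonnegative and (values < 0).any():
        t = series.index[int(np.argmax(values < 0))]
        raise ValueError(f"{name}: negative value at {t}")
    return series


@dataclass(frozen=True)
class ConversionParams:
    """Fixed factors of the power -> raw-biogas conversion.

    Defaults are the plant constants: CHP electrical efficiency 0.35,
    5.5 kWh per m^3 raw biogas, two digesters, and the full-demand scaling
    factor 4 (halved demand uses 2).
    """

    scaling_factor: float = 4.0
    chp_efficiency: float = 0.35
    kwh_per_m3: float = 5.5
    n_digesters: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.chp_efficiency <= 1.0:
            raise ValueError("chp_efficiency must be in (0, 1]")
        if self.kwh_per_m3 <= 0:
            raise ValueError("kwh_per_m3 must be positive")
        if self.n_digesters < 1:
            raise ValueError("n_digesters must be >= 1")
        if self.scaling_factor <= 0:
            raise ValueError("scaling_factor must be positive")


def seasonal_naive(history: pd.Series, horizon_h: int) -> np.ndarray:
    """Default forecaster: same hour, same weekday, previous week."""
    week = np.asarray(history, dtype=float)[-HOURS_PER_WEEK:]
    return week[np.arange(horizon_h) % HOURS_PER_WEEK]


def forecast_power(history: pd.Series, horizon_h: int = 48,
                   forecaster: Forecaster | None = None) -> pd.Series:
    """Forecast hourly power demand (kWh) for the next ``horizon_h`` hours.

    ``history`` must cover at least four gap-free weeks of hourly values.
    The forecaster is any callable ``(history, horizon_h) -> values``;
    negative outputs are clipped to zero with a logged warning.
    """
    check_hourly_series(history, "power history")
    if len(history) < MIN_HISTORY_H:
        raise ValueError(
            f"power history must span at least {MIN_HISTORY_H} hourly values "
            f"(4 weeks); got {len(history)}")
    if horizon_h < 1:
        raise ValueError("horizon_h must be >= 1")
    fn = seasonal_naive if forecaster is None else forecaster
    values = np.asarray(fn(history, horizon_h), dtype=float)
    if values.shape != (horizon_h,):
        raise ValueError(f"forecaster returned shape {values.shape}, "
                         f"expected ({horizon_h},)")
    if (values < 0).any():
        logger.warning("forecast contained %d negative values; clipped to 0",
                       int((values < 0).sum()))
        values = np.clip(values, 0.0, None)
    index = pd.date_range(history.index[-1] + pd.Timedelta(hours=1),
                          periods=horizon_h, freq="h")
    return pd.Series(values, index=index, name="power_kwh")


def power_to_biogas(power: pd.Series, params: ConversionParams,
                    scaling_factor: float | Sequence[float] | None = None,
                    ) -> pd.Series:
    """Convert hourly power demand (kWh) to raw-biogas demand (m^3/h).

    ``scaling_factor`` overrides ``params.scaling_factor``; it may be a
    per-hour array (used across demand-phase transitions, where the first
    hours of a horizon run at one factor and the rest at another).
    """
    check_hourly_series(power, "power series")
    fs = params.scaling_factor if scaling_factor is None else scaling_factor
    fs = np.asarray(fs, dtype=float)
    if fs.ndim not in (0, 1) or (fs.ndim == 1 and len(fs) != len(power)):
        raise ValueError("scaling_factor must be scalar or one value per hour")
    if (fs <= 0).any():
        raise ValueError("scaling_factor must be positive")
    coeff = fs / (params.chp_efficiency * params.kwh_per_m3) / params.n_digesters
    return pd.Series(np.asarray(power, dtype=float) * coeff,
                     index=power.index, name="biogas_m3")
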