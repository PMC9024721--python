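"""Synthetic full-scale digester and site demand generator.

Stands in for the research plant so the controller can be exercised
end-to-end without plant data.  The virtual digester produces gas as a
lagged linear response to solid feeding (a discretised first-order decay
kernel), plus a constant endogenous baseline, plus the response to one
daily bolus of liquid manure through its own faster kernel — a
disturbance the controller deliberately does not model — plus Gaussian
measurement noise, clipped at zero.

The demand generator tiles 24-h weekday/weekend mean profiles of the
site's electricity demand (day/night cycle, quieter weekends) with
additive Gaussian noise.  The default profiles are calibrated so that at
the full-demand scaling factor (f_s = 4, two digesters) the mean hourly
biogas demand is about 107 m^3/h.  Demand-phase scaling is applied at
conversion time by the closed loop, not here, so the generated series is
the raw site profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demand import ConversionParams, power_to_biogas

logger = logging.getLogger(__name__)

#: hourly mean site power demand, weekdays (kWh); night trough, working-day
#: plateau, evening decline.  Calibrated so that at f_s = 4 (two digesters)
#: the weekly-mean biogas demand is ~107 m^3/h, the full-demand extremes are
#: ~40-170 m^3/h, and the largest within-day demand spread stays near 95 m^3
DEFAULT_WEEKDAY_PROFILE = np.array(
    [72, 70, 69, 69, 71, 77,
     91, 112, 130, 140, 147, 149,
     148, 146, 144, 141, 138, 132,
     122, 112, 102, 94, 85, 78], dtype=float)
#: weekends run at ~78 % of the weekday profile
DEFAULT_WEEKEND_PROFILE = np.round(0.78 * DEFAULT_WEEKDAY_PROFILE, 1)

#: default experimental phase schedule: (duration_days, scaling_factor)
DEFAULT_PHASES = ((15, 4.0), (9, 2.0), (7, 4.0), (5, 2.0))


@dataclass
class DemandScenario:
    """Statistical shape of the site demand plus the phase schedule."""

    weekday_profile: np.ndarray = field(
        default_factory=lambda: DEFAULT_WEEKDAY_PROFILE.copy())
    weekend_profile: np.ndarray = field(
        default_factory=lambda: DEFAULT_WEEKEND_PROFILE.copy())
    noise_sd: float = 6.0
    phases: tuple = DEFAULT_PHASES

    def __post_init__(self) -> None:
        self.weekday_profile = np.asarray(self.weekday_profile, dtype=float)
        self.weekend_profile = np.asarray(self.weekend_profile, dtype=float)
        for name, prof in (("weekday", self.weekday_profile),
                           ("weekend", self.weekend_profile)):
            if prof.shape != (24,):
                raise ValueError(f"{name} profile must have 24 hourly values")
            if (prof < 0).any():
                raise ValueError(f"{name} profile must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.phases = tuple((int(d), float(f)) for d, f in self.phases)
        if any(d < 1 for d, _ in self.phases):
            raise ValueError("phase durations must be >= 1 day")
        if any(f <= 0 for _, f in self.phases):
            raise ValueError("phase scaling factors must be positive")

    @property
    def n_days(self) -> int:
        return sum(d for d, _ in self.phases)

    def scaling_factors(self, hours: np.ndarray) -> np.ndarray:
        """Scaling factor f_s per experiment hour.

        ``hours`` are hour offsets from the start of phase 1; negative
        offsets (warm-up) use the first phase's factor, offsets past the
        end use the last phase's.
        """
        bounds = np.cumsum([24 * d for d, _ in self.phases])
        factors = np.array([f for _, f in self.phases])
        idx = np.searchsorted(bounds, np.asarray(hours, dtype=int),
                              side="right")
        return factors[np.clip(idx, 0, len(factors) - 1)]


def generate_demand(scenario: DemandScenario, n_days: int,
                    seed: int | np.random.Generator = 0,
                    start: str | pd.Timestamp = "2022-01-03") -> pd.Series:
    """Hourly raw site power demand (kWh) over ``n_days`` days.

    Weekday/weekend profiles tiled over calendar days, plus additive
    Gaussian noise, clipped at 0.  Reproducible under ``seed``.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    index = pd.date_range(pd.Timestamp(start), periods=24 * n_days, freq="h")
    weekend = index.dayofweek >= 5
    base = np.where(weekend,
                    scenario.weekend_profile[index.hour],
                    scenario.weekday_profile[index.hour])
    values = base + rng.normal(0.0, scenario.noise_sd, size=base.size)
    return pd.Series(np.clip(values, 0.0, None), index=index,
                     name="power_kwh")


def exp_kernel(tau_h: float, length_h: int, total_m3_per_kg: float
               ) -> np.ndarray:
    """First-order-decay impulse response, scaled to a total specific yield."""
    if tau_h <= 0 or length_h < 1 or total_m3_per_kg < 0:
        raise ValueError("invalid kernel parameters")
    w = np.exp(-np.arange(length_h) / tau_h)
    return w * (total_m3_per_kg / w.sum())


@dataclass
class DigesterParams:
    """True (hidden) kinetics of the virtual digester."""

    kernel_total_m3_per_kg: float = 0.8   # specific yield of the solid mix
    kernel_tau_h: float = 8.0
    kernel_length_h: int = 24
    baseline_m3_h: float = 20.0           # endogenous production
    noise_sd_m3_h: float = 3.0
    manure_enabled: bool = True
    manure_kg_per_day: float = 6000.0
    manure_hour: int = 10                 # clock hour of the daily bolus
    manure_total_m3_per_kg: float = 0.025  # liquid manure's low specific yield
    manure_tau_h: float = 3.0
    manure_length_h: int = 12

    def solid_kernel(self) -> np.ndarray:
        return exp_kernel(self.kernel_tau_h, self.kernel_length_h,
                          self.kernel_total_m3_per_kg)

    def manure_kernel(self) -> np.ndarray:
        return exp_kernel(self.manure_tau_h, self.manure_length_h,
                          self.manure_total_m3_per_kg)


class VirtualDigester:
    """Hourly-stepped digester with internal feed history and clock.

    ``step_plant`` advances one hour: the solid feed for that hour enters
    the history, the daily manure bolus fires when the internal clock
    passes its hour, and the returned gas volume is the kernel response
    plus baseline plus noise, clipped at zero.
    """

    def __init__(self, params: DigesterParams | None = None,
                 seed: int | np.random.Generator = 0,
                 start_hour_of_day: int = 0) -> None:
        self.params = params if params is not None else DigesterParams()
        kernel = self.params.solid_kernel()
        if (kernel < 0).any() or self.params.baseline_m3_h < 0:
            raise ValueError("kernel and baseline must be non-negative")
        self.kernel = kernel
        self.manure_kernel_arr = self.params.manure_kernel()
        self.rng = (seed if isinstance(seed, np.random.Generator)
                    else np.random.default_rng(seed))
        self.start_hour_of_day = int(start_hour_of_day) % 24
        self._solid: list[float] = []
        self._manure: list[float] = []

    @property
    def t(self) -> int:
        """Hours elapsed."""
        return len(self._solid)

    def _response(self, history: list[float], kernel: np.ndarray) -> float:
        m = min(len(history), kernel.size)
        if m == 0:
            return 0.0
        recent = np.asarray(history[-m:], dtype=float)[::-1]
        return float(kernel[:m] @ recent)

    def step_plant(self, feed_now_kg: float) -> float:
        """Feed ``feed_now_kg`` of solids this hour; return the hour's gas (m^3)."""
        if feed_now_kg < 0:
            raise ValueError("feed must be >= 0")
        p = self.params
        hour_of_day = (self.start_hour_of_day + self.t) % 24
        manure = (p.manure_kg_per_day
                  if p.manure_enabled and hour_of_day == p.manure_hour else 0.0)
        self._solid.append(float(feed_now_kg))
        self._manure.append(manure)
        gas = (p.baseline_m3_h
               + self._response(self._solid, self.kernel)
               + self._response(self._manure, self.manure_kernel_arr))
        if p.noise_sd_m3_h > 0:
            gas += self.rng.normal(0.0, p.noise_sd_m3_h)
        return max(gas, 0.0)

    def run(self, feeds) -> np.ndarray:
        """Step through an array of hourly feeds; returns hourly gas."""
        return np.array([self.step_plant(f) for f in np.asarray(feeds, float)])


def warm_start(digester: VirtualDigester, power: pd.Series,
               conversion: ConversionParams,
               scaling_factor: float | None = None,
               increment_kg: float = 500.0,
               blackout: tuple[int, int] = (0, 3),
               seed: int | np.random.Generator = 0,
               ) -> tuple[pd.Series, pd.Series]:
    """Generate a self-consistent feed/gas history before day 1.

    Emulates the start-up phase run at conditions similar to the first
    experimental phase: each warm-up day the digester is fed roughly the
    solid mass needed to meet that day's biogas demand, as 500-kg events
    at random non-blackout hours, and the virtual digester produces the
    corresponding gas.  Returns hourly (feed_kg, gas_m3) series aligned
    with ``power``'s index.

    The mass target uses the digester's true kinetics — this is
    plant-side scaffolding, not controller knowledge.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    biogas = power_to_biogas(power, conversion, scaling_factor)
    p = digester.params
    kernel_sum = digester.kernel.sum()
    manure_daily = (p.manure_kg_per_day * p.manure_total_m3_per_kg
                    if p.manure_enabled else 0.0)
    n_days = len(power) // 24
    feeds = np.zeros(n_days * 24)
    bo_start, bo_len = blackout
    allowed = [h for h in range(24)
               if not (h - bo_start) % 24 < bo_len]
    for d in range(n_days):
        day_demand = float(biogas.iloc[d * 24:(d + 1) * 24].sum())
        mass = max(0.0, day_demand - 24 * p.baseline_m3_h - manure_daily)
        mass /= kernel_sum
        n_events = int(round(mass / increment_kg))
        for h in rng.choice(allowed, size=n_events, replace=True):
            feeds[d * 24 + int(h)] += increment_kg
    gas = digester.run(feeds)
    index = power.index[: n_days * 24]
    return (pd.Series(feeds, index=index, name="feed_kg"),
            pd.Series(gas, index=index, name="gas_m3"))
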