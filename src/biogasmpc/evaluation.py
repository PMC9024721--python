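"""Accuracy and balance metrics, reported per day and per phase.

The controller's own selection metric is the symmetric mean absolute
percentage error; for evaluation it is reported as a percentage
(SMAPE_Q), alongside the plain MAPE, the mean absolute error (m^3/h),
and the signed daily demand-production balance (m^3/day; positive means
overproduction, which the gas storage must absorb).  Each evaluated day
aggregates exactly 24 hourly observations.  The organic loading rate
(kg oDM per m^3 reactor volume per day) tracks process stability.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

HOURS_PER_DAY = 24

COMPARISONS = (("demand", "simulated"),
               ("simulated", "produced"),
               ("demand", "produced"))


def _pair(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1 or a.size < 1:
        raise ValueError(f"series lengths differ or are empty: "
                         f"{a.shape} vs {p.shape}")
    return a, p


def smape_q(actual, predicted) -> float:
    """Symmetric MAPE in percent: mean of |a-p|/(a+p) * 100.

    Hours where both values are zero contribute 0 (perfect match).
    Bounded in [0, 100]; symmetric in its arguments.
    """
    a, p = _pair(actual, predicted)
    denom = a + p
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, np.abs(a - p) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(ratio.mean() * 100.0)


def mape(actual, predicted) -> float:
    """Mean absolute percentage error in percent: mean of |a-p|/a * 100.

    Undefined when any actual value is zero — raises rather than
    silently skipping (use :func:`smape_q` for series that touch zero).
    """
    a, p = _pair(actual, predicted)
    if (a == 0).any():
        raise ValueError("MAPE is undefined for zero actual values; "
                         "filter them or use smape_q")
    return float(np.mean(np.abs(a - p) / a) * 100.0)


def mae(actual, predicted) -> float:
    """Mean absolute error, in the series' units (m^3/h here)."""
    a, p = _pair(actual, predicted)
    return float(np.mean(np.abs(a - p)))


def daily_diff(demand, produced) -> float:
    """Signed daily balance: sum of (produced - demand) in m^3.

    Positive values indicate overproduction, negative underproduction.
    """
    d, g = _pair(demand, produced)
    return float(np.sum(g - d))


def running_balance_extremum(demand, produced) -> float:
    """Largest absolute cumulative demand-production imbalance (m^3).

    The running balance is the prefix sum of (produced - demand); its
    extremum bounds the gas-storage capacity a schedule would need.
    """
    d, g = _pair(demand, produced)
    balance = np.cumsum(g - d)
    return float(np.max(np.abs(balance)))


def olr(daily_feed_kg, odm_fraction: float,
        reactor_volume_m3: float) -> np.ndarray:
    """Organic loading rate per day: feed * oDM fraction / volume.

    Units kg oDM m^-3 d^-1; ``daily_feed_kg`` is fresh mass fed per day.
    """
    if not 0.0 <= odm_fraction <= 1.0:
        raise ValueError("odm_fraction must be in [0, 1]")
    if reactor_volume_m3 <= 0:
        raise ValueError("reactor volume must be positive")
    feed = np.asarray(daily_feed_kg, dtype=float)
    if (feed < 0).any():
        raise ValueError("daily feed must be >= 0")
    return feed * odm_fraction / reactor_volume_m3


def daily_report(hourly: pd.DataFrame,
                 comparisons: Sequence[tuple[str, str]] = COMPARISONS,
                 ) -> pd.DataFrame:
    """Per-day metric table from an hourly frame.

    ``hourly`` must hold whole days (a multiple of 24 rows) of the
    columns named by ``comparisons`` (subset of demand / simulated /
    produced).  Returns one row per day per comparison with SMAPE_Q,
    MAPE, MAE and the signed daily difference; MAPE is NaN for days with
    zero-valued actuals.
    """
    n = len(hourly)
    if n == 0 or n % HOURS_PER_DAY:
        raise ValueError(f"hourly frame must hold whole days of "
                         f"{HOURS_PER_DAY} observations; got {n} rows")
    rows = []
    for day in range(n // HOURS_PER_DAY):
        sl = hourly.iloc[day * HOURS_PER_DAY:(day + 1) * HOURS_PER_DAY]
        for actual_col, pred_col in comparisons:
            if actual_col not in hourly or pred_col not in hourly:
                continue
            a, p = sl[actual_col], sl[pred_col]
            rows.append({
                "day": day + 1,
                "comparison": f"{actual_col}_vs_{pred_col}",
                "smape_pct": smape_q(a, p),
                "mape_pct": mape(a, p) if (a != 0).all() else np.nan,
                "mae_m3": mae(a, p),
                "diff_m3": daily_diff(a, p),
            })
    return pd.DataFrame(rows)


def assign_phases(daily: pd.DataFrame, phase_days: Sequence[int]
                  ) -> pd.DataFrame:
    """Attach a 1-based ``phase`` column from the scenario's durations."""
    bounds = np.cumsum(phase_days)
    out = daily.copy()
    out["phase"] = np.searchsorted(bounds, out["day"].to_numpy() - 1,
                                   side="right") + 1
    return out


def phase_summary(daily: pd.DataFrame, phase_days: Sequence[int]
                  ) -> pd.DataFrame:
    """Mean +/- SD of each metric per phase per comparison."""
    with_phase = assign_phases(daily, phase_days)
    metrics = ["smape_pct", "mape_pct", "mae_m3", "diff_m3"]
    grouped = with_phase.groupby(["comparison", "phase"])[metrics]
    summary = grouped.agg(["mean", "std"])
    summary.columns = [f"{m}_{stat}" for m, stat in summary.columns]
    return summary.reset_index()
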