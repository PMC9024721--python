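"""Distributed-lag regression simulator of biogas production.

Hourly gas output is modelled as a linear response to current and past
solid-substrate feedings,

    Y_t = alpha + beta_0 X_t + beta_1 X_{t-1} + ... + beta_k X_{t-k} + eps_t,

fitted by ordinary least squares on a rolling training window (default
the last 500 h of observation).  The intercept alpha absorbs endogenous
production the feed regressors cannot explain (residual degradation,
liquid-manure co-feeding — deliberately not a regressor).  Given the
recent feed history (the k pre-horizon lags) and a candidate timetable's
hourly masses, the horizon's production is the deterministic evaluation
of the fitted equation with eps_t = 0, clipped at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class TrainingWindow:
    """Aligned feed (kg/h) and gas (m^3/h) series over the training span."""

    feed: np.ndarray
    gas: np.ndarray

    def __post_init__(self) -> None:
        feed, gas = self.feed, self.gas
        if isinstance(feed, pd.Series) and isinstance(gas, pd.Series):
            if not feed.index.equals(gas.index):
                raise ValueError("feed and gas timestamps are not aligned")
        self.feed = np.asarray(feed, dtype=float)
        self.gas = np.asarray(gas, dtype=float)
        if self.feed.shape != self.gas.shape or self.feed.ndim != 1:
            raise ValueError("feed and gas must be 1-D series of equal length")
        if not (np.isfinite(self.feed).all() and np.isfinite(self.gas).all()):
            raise ValueError("training window contains non-finite values")

    def __len__(self) -> int:
        return len(self.feed)


@dataclass
class LagModel:
    """Fitted intercept and lag coefficients of the gas-response regression."""

    alpha: float
    betas: np.ndarray          # beta_0..beta_k, m^3 per kg at each lag hour
    residual_sd: float
    train_window_h: int
    alpha_se: float | None = None
    beta_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 1 or self.betas.size < 1:
            raise ValueError("betas must be a 1-D array beta_0..beta_k")
        if self.beta_se is not None:
            self.beta_se = np.asarray(self.beta_se, dtype=float)

    @property
    def k(self) -> int:
        """Lag order (hours)."""
        return self.betas.size - 1

    def dump(self, path: str | Path) -> None:
        """Write a flat key-value text file for audit and replay."""
        lines = [f"alpha={float(self.alpha)!r}", f"k={self.k}",
                 f"residual_sd={float(self.residual_sd)!r}",
                 f"train_window_h={self.train_window_h}"]
        lines += [f"beta_{j}={float(b)!r}" for j, b in enumerate(self.betas)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "LagModel":
        kv = {}
        for line in Path(path).read_text().splitlines():
            if line.strip():
                key, _, val = line.partition("=")
                kv[key.strip()] = val.strip()
        k = int(kv["k"])
        betas = np.array([float(kv[f"beta_{j}"]) for j in range(k + 1)])
        return cls(alpha=float(kv["alpha"]), betas=betas,
                   residual_sd=float(kv["residual_sd"]),
                   train_window_h=int(kv["train_window_h"]))


def fit_lag_model(win: TrainingWindow, k: int = 24,
                  ridge: float = 0.0) -> LagModel:
    """OLS fit of the distributed-lag model on a training window.

    The first ``k`` rows are dropped for lack of lags.  ``ridge`` > 0
    switches to ridge regression (intercept unpenalised) for collinear
    feed patterns; the default is plain OLS.
    """
    n = len(win)
    if k < 0:
        raise ValueError("lag order k must be >= 0")
    if n - k < k + 3:
        raise ValueError(f"training window of {n} h is too short to identify "
                         f"{k + 2} parameters (need > {2 * k + 3} h)")
    if np.var(win.feed) == 0:
        raise ValueError("feed regressor has zero variance (constant feed); "
                         "lag coefficients are not identifiable")
    # lagged design: column j holds X_{t-j} for t = k..n-1
    X = np.column_stack([win.feed[k - j: n - j] for j in range(k + 1)])
    y = win.gas[k:]
    if ridge > 0.0:
        Xc = X - X.mean(axis=0)
        A = Xc.T @ Xc + ridge * np.eye(k + 1)
        betas = np.linalg.solve(A, Xc.T @ (y - y.mean()))
        alpha = float(y.mean() - X.mean(axis=0) @ betas)
        resid = y - alpha - X @ betas
        dof = max(len(y) - (k + 2), 1)
        return LagModel(alpha=alpha, betas=betas,
                        residual_sd=float(np.sqrt(resid @ resid / dof)),
                        train_window_h=n)
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    if res.df_model < k + 1 - 1e-9:
        raise ValueError("rank-deficient design: feed lag columns are "
                         "linearly dependent over this window")
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    return LagModel(alpha=float(params[0]), betas=params[1:],
                    residual_sd=float(np.sqrt(res.mse_resid)),
                    train_window_h=n, alpha_se=float(bse[0]), beta_se=bse[1:])


def _extend(recent_feed: Sequence[float], future: np.ndarray,
            k: int) -> np.ndarray:
    recent = np.asarray(recent_feed, dtype=float)
    if recent.size < k:
        raise ValueError(f"recent_feed must supply at least k={k} lagged "
                         f"hours; got {recent.size}")
    tail = recent[recent.size - k:] if k else recent[:0]
    if future.ndim == 1:
        return np.concatenate([tail, future])
    return np.concatenate([np.broadcast_to(tail, (future.shape[0], k)),
                           future], axis=1)


def simulate_gas(model: LagModel, recent_feed: Sequence[float],
                 future_feed: Sequence[float]) -> np.ndarray:
    """Simulate hourly gas production (m^3/h) for one feeding plan.

    Deterministic evaluation of the lag equation with zero error term;
    negative predictions are clipped at 0 with a logged warning.
    """
    future = np.asarray(future_feed, dtype=float)
    ext = _extend(recent_feed, future, model.k)
    h = future.size
    out = np.full(h, model.alpha)
    for j, beta in enumerate(model.betas):
        out += beta * ext[model.k - j: model.k - j + h]
    if (out < 0).any():
        logger.warning("simulated gas went negative in %d hours; clipped to 0",
                       int((out < 0).sum()))
        out = np.clip(out, 0.0, None)
    return out


def simulate_gas_batch(model: LagModel, recent_feed: Sequence[float],
                       future_feeds: np.ndarray) -> np.ndarray:
    """Vectorised :func:`simulate_gas` over candidates (rows of kg/h)."""
    future = np.asarray(future_feeds, dtype=float)
    if future.ndim != 2:
        raise ValueError("future_feeds must be 2-D (candidates x hours)")
    ext = _extend(recent_feed, future, model.k)
    h = future.shape[1]
    out = np.full(future.shape, model.alpha)
    for j, beta in enumerate(model.betas):
        out += beta * ext[:, model.k - j: model.k - j + h]
    return np.clip(out, 0.0, None)
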