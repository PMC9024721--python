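"""Shared fixtures: small planted-model histories and closed-loop runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from biogasmpc import LoopConfig, run_closed_loop
from biogasmpc.gasmodel import LagModel


def hourly_index(n: int, start: str = "2022-01-03") -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n, freq="h")


def hourly_series(values, start: str = "2022-01-03") -> pd.Series:
    values = np.asarray(values, dtype=float)
    return pd.Series(values, index=hourly_index(len(values), start))


def lag_process(alpha: float, betas, n: int, rng: np.random.Generator,
                noise_sd: float = 0.0, p_feed: float = 0.2,
                increment: float = 500.0):
    """Generate (feed, gas) from a known distributed-lag process."""
    betas = np.asarray(betas, dtype=float)
    k = betas.size - 1
    feed = increment * (rng.random(n + k) < p_feed)
    gas = np.full(n, alpha)
    for j, b in enumerate(betas):
        gas += b * feed[k - j: k - j + n]
    if noise_sd > 0:
        gas += rng.normal(0.0, noise_sd, n)
    return feed[k:], gas


@pytest.fixture(scope="session")
def planted_model() -> LagModel:
    return LagModel(alpha=25.0, betas=np.array([0.30, 0.22, 0.15, 0.08, 0.05]),
                    residual_sd=0.0, train_window_h=600)


@pytest.fixture(scope="session")
def closed_loop_runs():
    """Default 36-day closed-loop runs for the first three seeds.

    Shared between the headline-accuracy and phase-asymmetry checks so the
    loop executes only three times per test session.
    """
    return {seed: run_closed_loop(LoopConfig(seed=seed)) for seed in (0, 1, 2)}
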