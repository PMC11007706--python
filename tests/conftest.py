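"""Shared fixtures: registry, params, and cached long simulations.

The three reference simulations (glucose drink, three-meal sequence,
consumption-rate sweep) are expensive; they are run once per session and
shared between the acceptance checks and the qualitative-ordering tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from gutsim import engine
from gutsim.core_state import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def params():
    return engine.default_params()


@pytest.fixture(scope="session")
def glucose_run():
    """50 g glucose in 250 mL water at 60 mL/min, 170 simulated minutes."""
    plan = engine.builtin_fixture("glucose-ogtt")
    cfg = engine.SimulationConfig(dt_s=1.0, duration_min=170.0)
    return engine.simulate(plan, None, cfg)


@pytest.fixture(scope="session")
def fig4_run():
    """Three-meal sequence (glucose, bread, pasta at 500-min spacing)."""
    plan = engine.builtin_fixture("fig4-sequence")
    cfg = engine.SimulationConfig(dt_s=1.0, duration_min=1400.0)
    return engine.simulate(plan, None, cfg)


@pytest.fixture(scope="session")
def sweep_run():
    """Bread block of the consumption-rate sweep (1..128 mL/min)."""
    plan = engine.builtin_fixture("fig5-sweep")
    cfg = engine.SimulationConfig(dt_s=1.0, duration_min=4000.0)
    return engine.simulate(plan, None, cfg)


def window_max(result, column, t0, t1):
    t = result.column("t_min")
    mask = (t >= t0) & (t < t1)
    return float(result.column(column)[mask].max())


def window_mean(result, column, t0, t1):
    t = result.column("t_min")
    mask = (t >= t0) & (t <= t1)
    return float(result.column(column)[mask].mean())
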