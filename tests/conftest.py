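"""Shared fixtures: small cached pipeline runs reused across test modules.

The cached runs use reduced history counts (a few thousand forced photon
histories) chosen so the whole suite finishes in minutes while keeping the
Monte-Carlo uncertainties small enough for the assertions made on them.
"""

from __future__ import annotations

import functools

import numpy as np
import pytest

from nanodef import pipelines as P

STEP1_HISTORIES = 6000
CELL_HISTORIES = 50000


@functools.lru_cache(maxsize=None)
def _two_step(model: str, energy: float, histories: int = STEP1_HISTORIES,
              seed: int = 101, b_tesla: float = 0.0):
    cfg = P.SimulationConfig(pipeline="two-step", np_model=model, energy_kev=energy,
                             histories=histories, seed=seed, b_tesla=b_tesla)
    return P.run_two_step(cfg)


@functools.lru_cache(maxsize=None)
def _cell(model: str, concentration: float, energy: float,
          histories: int = CELL_HISTORIES, seed: int = 202, placements: int = 1):
    cfg = P.SimulationConfig(pipeline="cell", np_model=model, energy_kev=energy,
                             concentration_mg_ml=concentration, histories=histories,
                             seed=seed, placement_seeds=placements)
    return P.run_cell(cfg)


@pytest.fixture(scope="session")
def two_step_run():
    """Callable (model, energy, **kw) -> cached two-step RunResult."""
    return _two_step


@pytest.fixture(scope="session")
def cell_run():
    """Callable (model, concentration, energy, **kw) -> cached cell RunResult."""
    return _cell


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
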