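"""Shared fixtures: datasets are generated programmatically, never stored."""

from __future__ import annotations

import logging

import numpy as np
import pytest

import emglift as eg
from emglift.features import WindowGrid

logging.getLogger("emglift").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_grid() -> WindowGrid:
    """Five 100 ms windows spanning ±150 ms around onset."""
    return WindowGrid(region_ms=(-150.0, 150.0))


@pytest.fixture(scope="session")
def toy_trials():
    """Small but realistic dataset: 3 subjects × 3 lifts per class."""
    cfg = eg.SimConfig(n_subjects=3, lifts_per_class=3, lift_duration=5.0,
                       onset_time=2.5, seed=7)
    return eg.generate_dataset(cfg)


@pytest.fixture(scope="session")
def toy_report(toy_trials, toy_grid):
    return eg.run_pipeline(toy_trials, toy_grid)


@pytest.fixture(scope="session")
def default_trials():
    """The full default protocol: 9 subjects × 30 lifts."""
    return eg.generate_dataset(eg.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_report(default_trials):
    """Full-grid (79-window) nested-LOSO run on the default dataset."""
    return eg.run_pipeline(default_trials)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
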