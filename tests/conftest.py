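"""Shared fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from sifted.energy_model import EnergyMatrix
from sifted.synthetic_data import (
    SimulationConfig,
    default_truth,
    simulate_panel,
    truth_em,
)
from sifted.tale_core import parse_rvd_string


@pytest.fixture(scope="session")
def small_protein():
    return parse_rvd_string("NI-HD-NN-NG-NI-HD")


@pytest.fixture(scope="session")
def random_em():
    """A seeded random anchored 8-column energy matrix."""
    rng = np.random.default_rng(20240101)
    vals = rng.uniform(0.0, 3.0, (8, 4))
    anchors = rng.integers(0, 4, 8)
    vals[np.arange(8), anchors] = 0.0
    return EnergyMatrix(values=vals, anchors=anchors)


@pytest.fixture(scope="session")
def truth_model():
    return default_truth()


@pytest.fixture(scope="session")
def small_panel(truth_model):
    """Six proteins, 8.5-14.5 repeats, with their ground-truth matrices."""
    cfg = SimulationConfig(panel_size=6, min_repeats=8.5, max_repeats=14.5, seed=7)
    proteins = simulate_panel(cfg)
    return [
        (p, truth_em(p, truth_model, seed=100 + i)) for i, p in enumerate(proteins)
    ]
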