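"""Shared fixtures: small simulated datasets and a trained classifier.

Session-scoped so the expensive simulations and the network fit run once;
every dataset is pinned by an explicit seed, so the suite is reproducible
run to run.
"""

from __future__ import annotations

import numpy as np
import pytest

from pgcc.beam import BeamModel
from pgcc.classifier import train
from pgcc.geometry import CameraGeometry
from pgcc.readout import ReadoutModel
from pgcc.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def geometry():
    return CameraGeometry()


@pytest.fixture(scope="session")
def clean_dataset():
    """Pileup-free labeled events (low dose rate), training-shuffled."""
    cfg = SimulationConfig(
        beam=BeamModel(dose_rate_kMU_per_min=2.0),
        n_emissions=6_000_000, seed=910, shuffle_training=True,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def pileup_dataset():
    """High-dose-rate labeled events with false and double-in-triple pileup."""
    cfg = SimulationConfig(
        beam=BeamModel(dose_rate_kMU_per_min=180.0),
        n_emissions=8_000_000, seed=911,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def trained_model():
    """Classifier fit on a moderate high-pileup shuffled dataset.

    Shared by the pipeline-level tests; trained once per session.
    """
    cfg = SimulationConfig(
        beam=BeamModel(dose_rate_kMU_per_min=180.0),
        n_emissions=50_000_000, seed=912, shuffle_training=True,
    )
    data = simulate(cfg)
    clf, _ = train(data, epochs=15, random_state=0)
    return clf


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
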