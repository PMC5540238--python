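"""Shared fixtures: small simulated ensembles reused across test modules."""

import numpy as np
import pytest

from chemoswim.physics import Medium
from chemoswim.simulate import SimulationConfig, gated_config, simulate_tracks
from chemoswim.swimmer import PropulsionLaw


@pytest.fixture(scope="session")
def body_medium():
    return Medium(temperature_K=310.15, viscosity_mPas=0.69)


@pytest.fixture(scope="session")
def passive_tracks():
    """2,000 passive 50 nm vesicle tracks, 30 fps, 1 s."""
    cfg = SimulationConfig(law=PropulsionLaw(0.0), n_particles=2000,
                           duration_s=1.0, seed=20260101)
    return simulate_tracks(cfg, fps=30.0)


@pytest.fixture(scope="session")
def gated_tracks():
    """Gated chemotactic ensemble (V0 = 168 μm/s, p = 10) in a uniform
    gradient along +x; 500 tracks, 30 fps, 1 s."""
    cfg = gated_config(168.0, n_particles=500, duration_s=1.0, seed=20260202)
    return simulate_tracks(cfg, fps=30.0)
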