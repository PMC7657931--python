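from datetime import date

import numpy as np
import pytest

from chronomove.simulate import SimulationConfig, simulate_tracks


@pytest.fixture(scope="session")
def winter_tracks():
    """Two individuals, two winter months, strong 12 h forcing."""
    cfg = SimulationConfig(n_individuals=2, start_date=date(2014, 1, 1),
                           end_date=date(2014, 2, 28), seed=11)
    return simulate_tracks(cfg), cfg


@pytest.fixture(scope="session")
def homogeneous_tracks():
    """Rhythm-free tracks from the baseline chain (for HMM recovery)."""
    cfg = SimulationConfig(n_individuals=4, start_date=date(2014, 1, 1),
                           end_date=date(2014, 2, 14),
                           ultradian_amp_winter=0.0, circadian_amp_max=0.0,
                           summer_forced_fraction=0.0, timeout_prob=0.0,
                           seed=23)
    return simulate_tracks(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
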