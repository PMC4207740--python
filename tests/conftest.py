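import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from chronosleep import SimulationConfig
from chronosleep.core import NREM, REM, WAKE, Hypnogram


@pytest.fixture(scope="session")
def config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_hypnogram(states, artifacts=None, start_zt=0.0, epoch_seconds=4.0) -> Hypnogram:
    states = np.asarray(states, dtype=np.int8)
    if artifacts is None:
        artifacts = np.zeros(states.size, dtype=bool)
    return Hypnogram(
        states=states,
        artifact_flags=np.asarray(artifacts, dtype=bool),
        epoch_seconds=epoch_seconds,
        start_zt=start_zt,
    )
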