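import numpy as np
import pytest

from gazestate.synthetic import (
    SimulationSpec,
    default_aois,
    default_profiles,
    simulate_dataset,
    simulate_gaze_stream,
)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def aois():
    return default_aois()


@pytest.fixture(scope="session")
def clean_stream(profiles, aois):
    """A zero-noise simulated gaze stream with its planted ground truth."""
    return simulate_gaze_stream(
        profiles[0], duration_s=10.0, sample_rate=120.0, seed=123, aois=aois, noise=False
    )


@pytest.fixture(scope="session")
def small_dataset():
    """8 participants x 3 states, 40-step series: quick but structured."""
    spec = SimulationSpec(n_participants=8, series_length=40, seed=5)
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def study_dataset():
    """Full study-scale dataset (26 x 3, 100 steps)."""
    return simulate_dataset(SimulationSpec(seed=17))
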