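import numpy as np
import pytest

from ppgbp.model import PreparedDataset
from ppgbp.preprocess import prepare_case
from ppgbp.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_sim_config() -> SimConfig:
    """Small but fully realistic generator settings for fast unit tests."""
    return SimConfig(n_subjects=8, cases_per_subject=2, seed=11)


@pytest.fixture(scope="session")
def tiny_recordings(tiny_sim_config):
    recordings, table = simulate_dataset(tiny_sim_config)
    return recordings, table


@pytest.fixture(scope="session")
def tiny_dataset(tiny_recordings) -> PreparedDataset:
    recordings, _ = tiny_recordings
    return PreparedDataset([prepare_case(r) for r in recordings])


@pytest.fixture(scope="session")
def noiseless_recording():
    """One clean case (no noise, no drift) for signal-level checks."""
    config = SimConfig(
        n_subjects=1, cases_per_subject=1, seed=5, noise_sd=0.0,
        drift_amplitude=0.0, bp_jitter=0.0,
    )
    recordings, _ = simulate_dataset(config)
    return recordings[0], config
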