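import numpy as np
import pytest

from rollgait import build_feature_table
from rollgait.simulate import SimulationConfig, simulate_cohort, simulate_trial


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_subjects=6, conditions=(0.0, 10.0, 20.0), trial_duration=30.0, seed=42
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    trials, _ = small_cohort
    return build_feature_table(trials)


@pytest.fixture(scope="session")
def clean_config():
    return SimulationConfig(
        n_subjects=6,
        conditions=(0.0, 10.0, 20.0),
        trial_duration=30.0,
        noise_sd=0.0,
        outcome_noise_sd=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    return simulate_cohort(clean_config)


@pytest.fixture(scope="session")
def clean_trial(clean_config):
    signal, truth = simulate_trial(clean_config, "S01", 20.0)
    return signal, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
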