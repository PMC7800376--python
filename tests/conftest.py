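import numpy as np
import pytest

from obstride import GeneratorConfig, generate_session
from obstride.pipeline import process_session
from obstride.sim.decisions import resolve_temperature


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(n_trials=50)


@pytest.fixture(scope="session")
def default_tau(default_config):
    return resolve_temperature(default_config)


@pytest.fixture(scope="session")
def small_session(default_config):
    """One default 50-trial session plus its planted truth."""
    raw, truth = generate_session(default_config, seed=1)
    return raw, truth


@pytest.fixture(scope="session")
def processed_session(small_session):
    raw, truth = small_session
    kin, steps = process_session(raw)
    return kin, steps, truth


@pytest.fixture(scope="session")
def noiseless_session():
    """Deterministic gait: no length noise, no speed spread, no tracking noise."""
    cfg = GeneratorConfig(n_trials=8, landing_noise_sd=0.0, speed_sd=0.0,
                          position_noise_sd=0.0, placement_sd=5.0,
                          decision_temperature=10.0)
    raw, truth = generate_session(cfg, seed=3)
    return cfg, raw, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
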