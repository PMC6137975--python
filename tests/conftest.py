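import numpy as np
import pytest

from epimem import pipeline, simulate
from epimem.config import RunConfig, SimConfig


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(seed=11)


@pytest.fixture(scope="session")
def dataset(sim_config):
    """One fully simulated experiment: (probes, genes, matrices, truth)."""
    probes, genes = simulate.simulate_probe_design(sim_config)
    matrices, truth = simulate.simulate_signals(probes, sim_config)
    return probes, genes, matrices, truth


@pytest.fixture(scope="session")
def experiment(sim_config, run_config):
    """Scored pipeline output plus ground truth at the default config."""
    result, truth = pipeline.simulate_and_score(sim_config, run_config)
    return result, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
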