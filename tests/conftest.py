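import numpy as np
import pandas as pd
import pytest

import pmtrack as pm


@pytest.fixture(scope="session")
def config():
    return pm.ExperimentConfig()


@pytest.fixture(scope="session")
def small_config():
    return pm.ExperimentConfig(n_cycles=2)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """6 participants x 2 cycles, paper-like effects, seed-pinned."""
    trials, trajectories, ground_truth = pm.simulate_experiment(
        small_config, pm.paper_like_effects(), 6, seed=12345
    )
    return trials, trajectories, ground_truth


@pytest.fixture(scope="session")
def small_measures(small_experiment, small_config):
    _, trajectories, _ = small_experiment
    norm = pm.normalize_trajectories(trajectories, small_config)
    return pm.compute_measures(norm)


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
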