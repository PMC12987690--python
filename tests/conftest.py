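import numpy as np
import pytest

from mstp.data_model import TrajectoryDataset
from mstp.policy import PolicyParams
from mstp.simulation import ScenarioConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset(rng):
    """4 subjects x 3 stages x 2 features, uniform behavior policy."""
    n, T, d = 4, 3, 2
    return TrajectoryDataset(
        features=rng.normal(size=(n, T, d)),
        actions=rng.choice([-1, 1], size=(n, T)),
        rewards=rng.normal(size=(n, T)),
        behavior_prob=np.full((n, T), 0.5),
    )


@pytest.fixture
def small_sim():
    """Modest Scenario 2 dataset under the behavior policy."""
    cfg = ScenarioConfig(scenario=2, n=60, T=2, d=4, seed=7)
    return simulate(cfg)


@pytest.fixture
def theta_small():
    return PolicyParams(np.array([0.1, 0.3, -0.2, 0.05, 0.0]), tau=0.2)
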