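import numpy as np
import pytest

from immunedag import DiscreteDataset, K2Scorer
from immunedag import benchmark as bm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """3-node, 200-row dataset from a known chain model (arity 3)."""
    rng = np.random.default_rng(7)
    truth = bm.random_dag(3, 2, rng)
    model = bm.sample_model(truth, 3, 0.2, rng)
    return bm.sample_observations(model, 200, rng)


@pytest.fixture(scope="session")
def recovery_instance():
    """The fixed strong-CPT 5-node/5-arc benchmark instance and its datasets."""
    rng = np.random.default_rng(0)
    truth = bm.random_dag(5, 5, rng)
    model = bm.sample_strong_model(truth, 3, 0.2, rng)
    datasets = {n: bm.sample_observations(model, n, rng) for n in (5000, 1000, 200)}
    return truth, model, datasets


def make_dataset(obs, arity=None):
    obs = np.asarray(obs, dtype=np.int64)
    if arity is None:
        arity = obs.max(axis=0)
    return DiscreteDataset(obs, np.asarray(arity, dtype=np.int64))
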