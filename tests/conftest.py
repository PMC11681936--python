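import numpy as np
import pytest

from peppinet.config import RunConfig
from peppinet.fixtures import FixtureSpec, make_planted_dataset
from peppinet.train_eval import train


@pytest.fixture(scope="session")
def embedding_dataset():
    """Planted-motif pair set: label = both members carry the motif channel."""
    return make_planted_dataset(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def structure_dataset():
    """Planted-geometry pair set: label = both members are helical."""
    return make_planted_dataset(FixtureSpec(seed=2, planted_rule="structure"))


@pytest.fixture(scope="session")
def test_config():
    return RunConfig.test_profile(seed=1, epochs=25)


@pytest.fixture(scope="session")
def trained(embedding_dataset, test_config):
    """One trained model + history, shared across the suite."""
    model, history = train(embedding_dataset, test_config)
    return model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
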