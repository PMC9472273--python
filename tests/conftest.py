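import numpy as np
import pytest

from screenbo import CampaignConfig, generate_linear_library


@pytest.fixture(scope="session")
def small_linear():
    """600-molecule linear pool for fast campaign tests."""
    return generate_linear_library(600, 10, 5, seed=11)


@pytest.fixture(scope="session")
def medium_linear():
    """1000-molecule linear pool for surrogate-quality tests."""
    return generate_linear_library(1000, 10, 5, seed=23)


def small_config(**overrides):
    """Desk-scale campaign defaults: batches of 50, 4 AL batches, 25 trees."""
    base = dict(batch_size=50, max_batches=4, n_trees=25)
    base.update(overrides)
    return CampaignConfig(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
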