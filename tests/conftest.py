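import numpy as np
import pytest

from fus2net import generate_dataset, small_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """40 reduced-resolution phantoms (20 per class) shared across tests."""
    return generate_dataset(small_config(20, 20, size=64, seed=11))


@pytest.fixture(scope="session")
def tiny_dataset_with_masks():
    cfg = small_config(25, 25, size=96, seed=21)
    return generate_dataset(cfg, with_masks=True)
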