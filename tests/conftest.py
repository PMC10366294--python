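import numpy as np
import pytest

from capmech import generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """60-sample synthetic dataset shared by fast tests."""
    return generate_dataset(60, n_nodes=60, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
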