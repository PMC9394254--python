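import numpy as np
import pytest

from cceeg.synthetic_data import desk_scale_config, generate_dataset, well_separated_config


@pytest.fixture(scope="session")
def desk_dataset():
    """Default-amplitude desk-scale dataset: 8 channels x 512 samples, 10/class."""
    return generate_dataset(desk_scale_config(epochs_per_class=10, seed=5))


@pytest.fixture(scope="session")
def separable_dataset():
    """Maximally separable desk-scale dataset for learning-behaviour checks."""
    return generate_dataset(well_separated_config(epochs_per_class=10, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
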