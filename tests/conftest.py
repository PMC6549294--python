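import warnings

import numpy as np
import pytest

from morphofun import (
    CalciumParams,
    FieldParams,
    MaturationModel,
    generate_calcium,
    generate_field,
    simulate_descriptor_table,
)

warnings.filterwarnings("ignore", category=FutureWarning, module="skimage")


@pytest.fixture(scope="session")
def small_field_params():
    """Compact renderable field used across image tests."""
    return FieldParams(
        shape=(3, 320, 320),
        n_neuronal=4,
        n_glial=1,
        n_pre_spots=18,
        n_post_spots=18,
        n_true_synapses=10,
    )


@pytest.fixture(scope="session")
def noiseless_field(small_field_params):
    img, truth = generate_field(small_field_params, seed=11, noise=False)
    return img, truth


@pytest.fixture(scope="session")
def noisy_field(small_field_params):
    img, truth = generate_field(small_field_params, seed=11)
    return img, truth


@pytest.fixture(scope="session")
def calcium_recording():
    params = CalciumParams(n_neurons=8, duration_s=120.0, synchrony_fraction=0.5)
    rec, truth = generate_calcium(params, seed=3)
    return rec, truth


@pytest.fixture(scope="session")
def descriptor_table():
    return simulate_descriptor_table(MaturationModel(), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
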