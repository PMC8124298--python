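import warnings

import numpy as np
import pytest

from nptarget.model import init_parameters
from nptarget.synthdata import SyntheticSpec, generate

warnings.filterwarnings("ignore", message="single-class labels")
warnings.filterwarnings("ignore", message=".*single-class targets excluded")


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down generator spec for fast training tests."""
    return SyntheticSpec(
        n_source=400, n_target=120, n_targets=8, n_bits=32, seed=11
    )


@pytest.fixture(scope="session")
def small_data(small_spec):
    return generate(small_spec)


@pytest.fixture()
def tiny_params():
    return init_parameters((6, 5, 4, 3), n_targets=4,
                           rng=np.random.default_rng(42))
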