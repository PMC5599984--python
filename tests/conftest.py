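import numpy as np
import pytest

from hippot2.phantom import PhantomSpec, generate_phantom
from hippot2.relaxometry import fit_t2_map

SMALL_SHAPE = (80, 80, 20)
MID_SHAPE = (96, 96, 24)


@pytest.fixture(scope="session")
def phantom_clean():
    """Noiseless mid-size phantom shared across tests."""
    return generate_phantom(PhantomSpec(shape=MID_SHAPE, noise_sigma=0.0))


@pytest.fixture(scope="session")
def t2map_clean(phantom_clean):
    return fit_t2_map(phantom_clean.acquisition)


@pytest.fixture(scope="session")
def phantom_noisy():
    """Rician-noise phantom at the default sigma (late-echo SNR ~ 55)."""
    return generate_phantom(
        PhantomSpec(shape=MID_SHAPE, noise_sigma=5.0, seed=7)
    )


@pytest.fixture(scope="session")
def t2map_noisy(phantom_noisy):
    return fit_t2_map(phantom_noisy.acquisition)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
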