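import numpy as np
import pytest

from fourierpd import PhantomConfig, make_complex_phantom, make_varden1d_mask


@pytest.fixture(scope="session")
def phantom64():
    """One deterministic noiseless 64^2 complex phantom."""
    return make_complex_phantom(PhantomConfig(grid_size=64, seed=7))


@pytest.fixture(scope="session")
def mask64():
    """1D Varden 25% mask on the 64^2 grid."""
    return make_varden1d_mask((64, 64), 0.25, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
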