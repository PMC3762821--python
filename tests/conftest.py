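import numpy as np
import pytest

from ctrestore import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom():
    """Default 64x64x10 phantom: Gaussian blur sigma=2, noise std 5."""
    return make_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def clean_phantom():
    """Undegraded phantom with well-separated sparse features."""
    return make_phantom(
        PhantomSpec(blur=None, noise_std=0.0, sparse_amplitude=400.0,
                    sparse_fraction=0.02, seed=7)
    )
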