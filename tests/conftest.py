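import numpy as np
import pytest

from sxtseg import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A small but complete phantom shared across tests (read-only)."""
    spec = PhantomSpec(shape=(70, 120, 80), n_mito=6, n_vesicles=20, seed=1)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom_clean():
    """Noise-free variant of the small phantom, for exact LAC checks."""
    spec = PhantomSpec(shape=(70, 120, 80), n_mito=6, n_vesicles=20, seed=1,
                       noise_sd=0.0)
    return generate_phantom(spec)
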