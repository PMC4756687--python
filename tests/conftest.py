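import numpy as np
import pytest

from srfdenoise import PhantomSpec, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def texture(rng):
    """Small non-degenerate image: all pairwise regional distances > 0."""
    return rng.uniform(0.0, 10.0, size=(16, 16))


@pytest.fixture(scope="session")
def small_phantom_pair():
    """One 64x64 (truth, noisy) phantom pair at beta = 0.5."""
    spec = PhantomSpec(size=(64, 64), beta=0.5, seed=5)
    (truth, noisy), = make_dataset(spec, [0.5], seed=5)
    return spec, truth, noisy
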