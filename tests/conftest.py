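import numpy as np
import pytest

from edgeinterp import GrayImage, PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """Seeded smooth-ish random image (values strictly inside [0, 1])."""
    base = rng.uniform(0.1, 0.9, size=(32, 32))
    return GrayImage(base)


@pytest.fixture
def vertical_step():
    """Left half 0.2, right half 0.8, 1-px anti-aliased boundary."""
    return make_phantom(PhantomSpec("oriented_step", (32, 32), {"angle": 90.0}))


@pytest.fixture
def constant_image():
    return GrayImage(np.full((24, 24), 0.6))
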