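import numpy as np
import pytest

from nfmo import ColorImage, FixtureSpec, generate


@pytest.fixture
def constant_image() -> ColorImage:
    return generate(FixtureSpec("constant", size=(32, 32)))


@pytest.fixture
def random_image() -> np.ndarray:
    """A small random-content colour image (arbitrary, reproducible)."""
    rng = np.random.default_rng(1234)
    return rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
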