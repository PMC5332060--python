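import numpy as np
import pytest

from srsc.io_model import DEFAULT_PARAMS, MultiparametricStack
from srsc.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A 12x12x6 concentric-shell phantom with mild noise."""
    spec = PhantomSpec(shape=(12, 12, 6), seed=7, noise_multiplier=0.5)
    stack, labels, fractions = generate_phantom(spec)
    return stack, labels, fractions


@pytest.fixture
def full_mask_stack():
    """An 8x8x4 stack with a full mask and seeded random maps."""
    rng = np.random.default_rng(42)
    shape = (8, 8, 4)
    maps = {p: rng.normal(50.0, 10.0, shape) for p in DEFAULT_PARAMS}
    return MultiparametricStack(maps=maps, mask=np.ones(shape, dtype=bool))
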