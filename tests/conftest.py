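import numpy as np
import pytest

from frozenframes import FrameStack, make_filter_pair


@pytest.fixture
def constant_stack():
    return FrameStack(np.full((10, 8, 8), 50.0), fps=25.0)


@pytest.fixture
def random_stack():
    rng = np.random.default_rng(7)
    return FrameStack(rng.uniform(0, 255, size=(12, 16, 16)), fps=25.0)


@pytest.fixture
def small_pair():
    """An (LL, LH) filter pair sized for tiny test stacks."""
    return make_filter_pair(rho_std=1.0, phi_kind="box", phi_size=2)


@pytest.fixture
def gaussian_pair():
    """Smooth temporal pair for minima/zeros duality checks."""
    return make_filter_pair(rho_std=2.0, phi_kind="gaussian", phi_size=8)
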