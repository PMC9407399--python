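import numpy as np
import pytest

from entroseg.phantom import PhantomConfig, generate_phantom
from entroseg.selection import SelectionParams


@pytest.fixture(scope="session")
def small_phantom():
    """A small labelled volume with a couple of aneurysms (128x128 in-plane)."""
    return generate_phantom(
        PhantomConfig(depth=24, height=128, width=128, n_aneurysms=2, seed=5)
    )


@pytest.fixture(scope="session")
def default_params():
    return SelectionParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
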