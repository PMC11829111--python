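import numpy as np
import pytest

from desire.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_case():
    """One deterministic phantom on the smallest grid the geometry allows."""
    return generate_phantom(PhantomSpec(grid_shape=(32, 32, 32), n_oars=2, seed=7))


@pytest.fixture(scope="session")
def default_case():
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
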