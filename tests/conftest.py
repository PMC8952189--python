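import numpy as np
import pytest

from octadr.synthetic import generate_phantom, ndr_spec


@pytest.fixture(scope="session")
def phantom128():
    """One seeded healthy phantom used across modules."""
    return generate_phantom(ndr_spec(128, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
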