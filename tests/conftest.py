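import numpy as np
import pytest

from vesselthresh.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default-condition phantom shared across tests."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
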