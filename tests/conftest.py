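import numpy as np
import pytest

from pararep.kinetics import KineticParams
from pararep.sequences import generate_master_set


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def master_set():
    """A fixed random master set (T=10, L=10, pairwise Hamming >= 2)."""
    return generate_master_set(10, 10, seed=42)


@pytest.fixture
def kp():
    return KineticParams()
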