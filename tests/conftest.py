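import numpy as np
import pytest

from pulsecount.detector_response import make_kernel


@pytest.fixture(scope="session")
def scint_kernel():
    """Scintillator pulse kernel at the 8 ns ADC clock."""
    return make_kernel(kind="scintillator")


@pytest.fixture(scope="session")
def solid_kernel():
    return make_kernel(kind="solid_state")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
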