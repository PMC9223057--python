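import numpy as np
import pytest

from somnowave.filterbank import DesignSpec, design_filter_bank
from somnowave.synthetic import SynthSpec, simulate_recording


@pytest.fixture(scope="session")
def bank18():
    """The 18-tap, 3-vanishing-moment filter bank used throughout."""
    return design_filter_bank(DesignSpec(length=18, vanishing_moments=3))


@pytest.fixture(scope="session")
def bank4():
    """A small (fast to design) 4-tap bank for transform-level tests."""
    return design_filter_bank(DesignSpec(length=4, vanishing_moments=1))


@pytest.fixture(scope="session")
def haar_bank():
    return design_filter_bank(DesignSpec(length=2, vanishing_moments=1))


@pytest.fixture(scope="session")
def small_recording():
    """600 synthetic epochs at the default signal strength."""
    return simulate_recording(SynthSpec(n_epochs=600, seed=7, snr=3.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
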