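import numpy as np
import pytest

from rotadapt.model import TuningField

GAMMA30 = np.deg2rad(30.0)
E0_30 = 2.0 * (1.0 - np.cos(GAMMA30))  # pre-adaptation noiseless error, 30 deg rotation


@pytest.fixture(scope="session")
def field60():
    """Small input layer used by simulation-heavy tests."""
    return TuningField(N=60, rho=1.0)


@pytest.fixture(scope="session")
def field360():
    """Dense input layer used by analytic-accuracy tests."""
    return TuningField(N=360, rho=1.0)
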