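import numpy as np
import pytest

from myelosim import calibration


@pytest.fixture(scope="session")
def params():
    """The calibrated healthy-adult parameter set (noise off)."""
    return calibration.default_parameters()


@pytest.fixture(scope="session")
def params_noisy():
    """Calibrated parameters with the default overdispersion switched on."""
    return calibration.default_parameters(gamma=0.03)


@pytest.fixture()
def rng():
    return np.random.default_rng(20181001)
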