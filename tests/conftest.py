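import numpy as np
import pytest

from tpbecm.dielectric import default_frequency_grid
from tpbecm.fixtures import forearm_body, gen_agar_pair
from tpbecm.network import calibrate_scale


@pytest.fixture(scope="session")
def freq_grid():
    """The 201-point 0.1 Hz-10 kHz log measurement grid."""
    return default_frequency_grid()


@pytest.fixture(scope="session")
def forearm():
    """Baseline skin/fat/muscle forearm with the default (unit) IF scale."""
    return forearm_body()


@pytest.fixture(scope="session")
def forearm_calibrated():
    """Forearm with the IF scale anchored to a 30 kOhm low-frequency skin layer."""
    body = forearm_body()
    scale = calibrate_scale(body, "skin_dry", target_ohm=30e3, frequency=0.1)
    return forearm_body(calibration_scale=scale)


@pytest.fixture(scope="session")
def agar_pair():
    return gen_agar_pair(seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)
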