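import numpy as np
import pytest

from nigranet.neuron_model import NeuronParams, calibrate_drive


@pytest.fixture(scope="session")
def params25():
    """Default pacemaker calibrated to 25 Hz (shared; calibration is slow)."""
    return calibrate_drive(NeuronParams(), 25.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
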