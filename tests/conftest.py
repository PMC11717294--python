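import numpy as np
import pytest

from chopgrip.datatypes import TrialProtocol
from chopgrip.simulate import generate_grip_sequence


@pytest.fixture(scope="session")
def noiseless_protocol():
    return TrialProtocol(noise_sd_px=0.0, dropout_rate=0.0)


@pytest.fixture(scope="session")
def short_noiseless_protocol():
    return TrialProtocol(duration_s=1.0, noise_sd_px=0.0, dropout_rate=0.0)


@pytest.fixture(scope="session")
def four_finger_sequence(noiseless_protocol):
    return generate_grip_sequence("four_finger", noiseless_protocol, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
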