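import numpy as np
import pytest

from renodiff.fitting import average_directions
from renodiff.signal_models import predict_biexp, predict_triexp
from renodiff.synthetic_data import PRESETS, protocol_scheme


@pytest.fixture(scope="session")
def ivim_scheme():
    return protocol_scheme("ivim")


@pytest.fixture(scope="session")
def dti_scheme():
    return protocol_scheme("dti")


@pytest.fixture(scope="session")
def cortex():
    return PRESETS["healthy_cortex"]


@pytest.fixture(scope="session")
def cyst():
    return PRESETS["cyst"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def noise_free_triexp(preset, scheme, s0=100.0, mode="geometric"):
    """Direction-averaged noise-free tri-exponential decay of a preset."""
    sig = predict_triexp(preset.triexp_params(s0=s0), scheme.bvalues)
    return average_directions(sig, scheme, mode)


def noise_free_biexp(preset, scheme, s0=100.0, mode="geometric"):
    sig = predict_biexp(preset.biexp_params(s0=s0), scheme.bvalues)
    return average_directions(sig, scheme, mode)
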