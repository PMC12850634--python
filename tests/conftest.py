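import numpy as np
import pytest

from vfamap.phantom import default_spec, generate_phantom
from vfamap.signal_model import AcquisitionProtocol, TissueParams


@pytest.fixture(scope="session")
def in_vivo_protocol():
    return AcquisitionProtocol.in_vivo_7t()


@pytest.fixture(scope="session")
def postmortem_protocol():
    return AcquisitionProtocol.postmortem_7t()


@pytest.fixture(scope="session")
def wm_tissue():
    return TissueParams(r1_per_s=0.82, a_au=1.0)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """32^3 noiseless two-compartment phantom, in vivo protocol."""
    return generate_phantom(default_spec(shape=(32, 32, 32), noise_sd=0.0, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
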