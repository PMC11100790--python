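import numpy as np
import pytest

from ecmfluor import synthetic
from ecmfluor.photophysics import AcquisitionSettings


@pytest.fixture(scope="session")
def default_dye():
    return synthetic.make_default_dye()


@pytest.fixture(scope="session")
def red_settings():
    """561 nm excitation with 575 nm longpass detection."""
    return AcquisitionSettings(excitation_nm=561.0, emission_band=(575.0, None))


@pytest.fixture(scope="session")
def green_settings():
    """488 nm excitation with a 500-545 nm emission band."""
    return AcquisitionSettings(excitation_nm=488.0, emission_band=(500.0, 545.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
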