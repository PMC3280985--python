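import numpy as np
import pytest

from herggating.calibration import WT_REFERENCE, calibrate_construct
from herggating.params import WT_PARAMS
from herggating.synth import generate_mutant_library


@pytest.fixture(scope="session")
def wt_calibration():
    """WT prefactors calibrated from the reference characteristics.

    Shared across tests because the calibration is the most expensive
    single step; it is exercised as its own test too.
    """
    return calibrate_construct(WT_REFERENCE["v05"], WT_REFERENCE["slope"],
                               WT_REFERENCE["tau_act"],
                               WT_REFERENCE["tau_deact"])


@pytest.fixture(scope="session")
def library():
    return generate_mutant_library()


@pytest.fixture(scope="session")
def wt_params():
    return WT_PARAMS


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
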