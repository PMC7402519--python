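import numpy as np
import pytest

from canatrial.cell_model import CellParameters, default_stimulus
from canatrial.remodelling import apply_remodelling, hf_default_config


@pytest.fixture(scope="session")
def control_params():
    return CellParameters()


@pytest.fixture(scope="session")
def hf_params(control_params):
    return apply_remodelling(control_params, hf_default_config())


@pytest.fixture(scope="session")
def control_stimulus(control_params):
    # twice diastolic threshold, resolved once per session
    return default_stimulus(control_params)


@pytest.fixture(scope="session")
def hf_stimulus(hf_params):
    return default_stimulus(hf_params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
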