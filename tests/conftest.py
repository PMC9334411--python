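import warnings

import numpy as np
import pytest

from oddballerp.iohub import RunConfig
from oddballerp.synthdata import make_lead_field

warnings.filterwarnings("ignore", message=".*FastICA did not converge.*")


@pytest.fixture(scope="session")
def lead_field():
    return make_lead_field()


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
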