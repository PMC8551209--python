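import numpy as np
import pytest

from dbsloop.params import NetworkParams, SmcInputParams, apply_condition


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def healthy_params():
    return apply_condition(NetworkParams(), "healthy")


@pytest.fixture()
def pd_params():
    return apply_condition(NetworkParams(), "pd")


@pytest.fixture()
def smc_params():
    return SmcInputParams()
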