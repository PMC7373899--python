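import numpy as np
import pytest

from ifnstat import build_network, nominal_parameters


@pytest.fixture(scope="session")
def network():
    return build_network()


@pytest.fixture(scope="session")
def nominal():
    # anchor verification has its own dedicated test
    return nominal_parameters(verify=False)


@pytest.fixture(scope="session")
def grid_24h():
    return np.arange(0.0, 24.01, 0.5)
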