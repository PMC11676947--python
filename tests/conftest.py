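import numpy as np
import pytest

from thalmf import InputConnectivity, TFCoefficients, cell_preset


@pytest.fixture(scope="session")
def tc_awake():
    return cell_preset("TC_awake")


@pytest.fixture(scope="session")
def re_awake():
    return cell_preset("RE_awake")


@pytest.fixture(scope="session")
def ic_tc(tc_awake):
    """TC input connectivity at the default thalamic in-degrees (K = pN = 25)."""
    return InputConnectivity(K_e=25.0, K_i=25.0, params=tc_awake)


@pytest.fixture(scope="session")
def ic_re(re_awake):
    return InputConnectivity(K_e=25.0, K_i=150.0, params=re_awake)


@pytest.fixture(scope="session")
def tf_tc():
    return TFCoefficients.reference("TC")


@pytest.fixture(scope="session")
def tf_re():
    return TFCoefficients.reference("RE")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
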