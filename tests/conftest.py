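import numpy as np
import pytest

from perispect.params import AcquisitionParams, default_priors


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def mets(priors):
    return list(priors.metabolites)


@pytest.fixture(scope="session")
def water(priors):
    return priors.water


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
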