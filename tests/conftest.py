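import numpy as np
import pytest

from ivimdnn.core import AcquisitionScheme, ParamRanges
from ivimdnn.phantom import PhantomTemplate, generate_phantom


@pytest.fixture(scope="session")
def scheme():
    return AcquisitionScheme()


@pytest.fixture(scope="session")
def ranges():
    return ParamRanges()


@pytest.fixture(scope="session")
def template():
    return PhantomTemplate.build()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noisy_phantom(template, scheme, ranges):
    """One SNR-25 phantom, shared by read-only tests."""
    return generate_phantom(template, scheme, ranges, snr=25,
                            rng=np.random.default_rng(99))
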