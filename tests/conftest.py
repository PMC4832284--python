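import numpy as np
import pytest

from sfmp import ScrfParams, build_dictionary


@pytest.fixture(scope="session")
def params():
    return ScrfParams()


@pytest.fixture(scope="session")
def dict600(params):
    """Shared dictionary for the standard 60-s, 10 Hz window."""
    return build_dictionary(600, 10.0, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20150430)
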