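import pytest

from uiascreen import make_default_params, make_lifetable


@pytest.fixture(scope="session")
def lifetable():
    return make_lifetable()


@pytest.fixture(scope="session")
def calibrated_params():
    return make_default_params("calibrated")


@pytest.fixture(scope="session")
def maintext_params():
    return make_default_params("main-text")
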