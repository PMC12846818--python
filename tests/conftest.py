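import warnings

import pytest

from instmfa.fixtures import make_fixture


@pytest.fixture(autouse=True)
def _quiet_runtime_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def toy():
    return make_fixture("toy_tca_glyox")


@pytest.fixture(scope="session")
def mini_auto():
    return make_fixture("mini_chlamy_auto")


@pytest.fixture(scope="session")
def mini_mixo():
    return make_fixture("mini_chlamy_mixo")
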