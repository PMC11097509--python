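import pytest

from oncoyield.fixture import paper_fixture


@pytest.fixture(scope="session")
def fixture_bundle():
    return paper_fixture()


@pytest.fixture(scope="session")
def cohort(fixture_bundle):
    return fixture_bundle.cohort


@pytest.fixture(scope="session")
def kb(fixture_bundle):
    return fixture_bundle.kb
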