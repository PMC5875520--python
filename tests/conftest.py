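import pytest

from kermastack import leksell4c_fixture


@pytest.fixture(scope="session")
def leksell():
    return leksell4c_fixture()


@pytest.fixture(scope="session")
def capsule(leksell):
    return leksell.capsule


@pytest.fixture(scope="session")
def geometry(leksell):
    return leksell.geometry
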