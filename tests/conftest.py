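import pytest

from mereokit.fixtures import make_exemplars, make_molecule


@pytest.fixture(scope="session")
def exemplars():
    return make_exemplars()


@pytest.fixture()
def water_flat():
    return make_molecule("H2O")


@pytest.fixture()
def water_nested():
    return make_molecule("H2O", nested=True)


@pytest.fixture()
def peroxide():
    return make_molecule("H2O2")
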