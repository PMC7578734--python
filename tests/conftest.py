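import pytest

from acumine import build_csap_fixture, builtin_registry, from_itemsets


@pytest.fixture(scope="session")
def csap():
    """The reconstructed 27-prescription chronic-stable-angina dataset."""
    return build_csap_fixture()


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture()
def toy_dataset():
    """Two prescriptions over two acupoints."""
    return from_itemsets({"S1": ["PC6", "LU9"], "S2": ["PC6"]})
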