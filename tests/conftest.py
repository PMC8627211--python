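import pytest

from hegcodon import load_code
from hegcodon.synth import make_reference_db


@pytest.fixture(scope="session")
def code():
    return load_code(11)


@pytest.fixture(scope="session")
def small_refdb():
    """8 families x 2 entries; enough structure for search tests."""
    return make_reference_db(8, 2, seed=7)


@pytest.fixture(scope="session")
def full_refdb():
    """All 40 families, 2 entries each."""
    return make_reference_db(40, 2, seed=7)
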