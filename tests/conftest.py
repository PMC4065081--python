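import random

import pytest

from venomtx.catalog import load_catalog
from venomtx.simulate import default_templates


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture()
def rng():
    return random.Random(20240620)
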