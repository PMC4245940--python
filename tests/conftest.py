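import numpy as np
import pytest

from nucleocpd.datasets import site_table
from nucleocpd.synthetic import HelixSpec, generate_helix_coordinates


@pytest.fixture(scope="session")
def table():
    return site_table()


@pytest.fixture(scope="session")
def helix_structure():
    return generate_helix_coordinates(HelixSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
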