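import numpy as np
import pytest

from bondpercept import Molecule, default_tables


@pytest.fixture(scope="session")
def tables():
    return default_tables()


@pytest.fixture(scope="session")
def radii(tables):
    return tables[0]


@pytest.fixture(scope="session")
def lengths(tables):
    return tables[1]


@pytest.fixture(scope="session")
def valences(tables):
    return tables[2]


def make_molecule(elements, coords):
    return Molecule.from_arrays(elements, np.asarray(coords, dtype=float))


@pytest.fixture
def molecule_factory():
    return make_molecule
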