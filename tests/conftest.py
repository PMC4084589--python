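import numpy as np
import pytest

from protdesc import (PhysicochemicalProperty, ProteinRecord,
                      bundled_property_table, load_substitution_matrix)
from protdesc.core import CANONICAL_ORDER
from protdesc.synthetic import random_protein


@pytest.fixture(scope="session")
def properties():
    return bundled_property_table()


@pytest.fixture(scope="session")
def prop(properties):
    """One physicochemical property (the hydropathy scale)."""
    return properties[0]


@pytest.fixture(scope="session")
def dayhoff():
    return load_substitution_matrix("DAYHOFF")


@pytest.fixture
def rng():
    return np.random.default_rng(20140615)


def make_record(rng, length, record_id="rnd"):
    """A uniformly random canonical protein of the given length."""
    return random_protein(length, np.full(20, 0.05), rng,
                          record_id=record_id)


@pytest.fixture
def simple_prop():
    """A property with index(a) = 1-based alphabet position, for hand
    calculations."""
    return PhysicochemicalProperty(
        id="POS", values={a: float(i + 1)
                          for i, a in enumerate(CANONICAL_ORDER)})


@pytest.fixture
def repeat_record():
    """Three alphabet repeats: length 60, every residue present."""
    return ProteinRecord("rep", CANONICAL_ORDER * 3)
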