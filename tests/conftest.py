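import numpy as np
import pytest

import inoise
from inoise import models


@pytest.fixture(scope="session")
def birth_death():
    return models.birth_death(k_in=1.0, k_out=0.1, omega=100.0)


@pytest.fixture(scope="session")
def linear_gene():
    return models.linear_gene()


@pytest.fixture(scope="session")
def dimer():
    return models.dimerization(omega=10.0)


@pytest.fixture(scope="session")
def enzyme():
    return models.enzyme_cycle(delta=0.5, omega=20.0)


@pytest.fixture(scope="session")
def autoreg():
    return models.autoreg_model()


@pytest.fixture(scope="session")
def autoreg_reduction(autoreg):
    return inoise.conservation_analysis(autoreg)


@pytest.fixture(scope="session")
def srna_i():
    return models.srna_model("i", alpha=1.0)


@pytest.fixture(scope="session")
def isomerization():
    return inoise.build_network(
        [("A", 1.0), ("B", 0.0)],
        [({"A": 1}, {"B": 1}, 2.0, "fwd"), ({"B": 1}, {"A": 1}, 1.0, "rev")],
        omega=50.0, name="isomerization")


def assert_allclose(a, b, **kw):
    np.testing.assert_allclose(a, b, **kw)
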