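import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from diapart.bench import random_system
from diapart.dia import ThermoConditions
from diapart.ising import build_lattice


@pytest.fixture(scope="session")
def lat4():
    return build_lattice(4)


@pytest.fixture(scope="session")
def lat3():
    return build_lattice(3)


@pytest.fixture()
def cond():
    return ThermoConditions(temperature=1.3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def make_system():
    """Seeded random heterogeneous system factory."""

    def _make(n, seed=0, heterogeneity=1.0):
        return random_system(n, seed=seed, heterogeneity=heterogeneity)

    return _make
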