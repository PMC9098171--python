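import numpy as np
import pytest

from setsolv.forcefield import load_default_forcefield, make_ion

ION_SPECS = [
    ("Li+", 1), ("Na+", 1), ("K+", 1), ("Cs+", 1),
    ("Cl-", -1), ("Br-", -1), ("I-", -1), ("NO3-", -1), ("SCN-", -1),
]


@pytest.fixture(scope="session")
def ff():
    return load_default_forcefield()


@pytest.fixture(scope="session")
def ff_ions(ff):
    return ff.with_beads(*(make_ion(name, q) for name, q in ION_SPECS))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
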