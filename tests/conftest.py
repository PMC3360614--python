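import numpy as np
import pytest

from mirest.energy import default_model
from mirest.io import load_catalogue


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def catalogue():
    return load_catalogue()


@pytest.fixture(scope="session")
def catalogue_by_name(catalogue):
    # the catalogue prints one duplicated name; keep the first occurrence
    out = {}
    for m in catalogue:
        out.setdefault(m.name, m)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20120525)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), n))


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))
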