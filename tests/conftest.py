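import numpy as np
import pytest

from degradome.catalogue import load_catalogue


@pytest.fixture(scope="session")
def catalogue():
    return load_catalogue()


@pytest.fixture(scope="session")
def inventory(catalogue):
    return catalogue.records


@pytest.fixture()
def rng():
    return np.random.default_rng(20210112)


def random_protein(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(
        alphabet[i] for i in rng.integers(0, len(alphabet), size=length)
    )
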