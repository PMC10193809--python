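import numpy as np
import pytest

from mtaltorf.genetic_code import load_code


@pytest.fixture(scope="session")
def mito_mod():
    return load_code("vertebrate_mito_modified")


@pytest.fixture(scope="session")
def mito():
    return load_code("vertebrate_mito")


@pytest.fixture(scope="session")
def standard():
    return load_code("standard")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230518)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[k] for k in rng.integers(0, 4, size=n))
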