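import numpy as np
import pytest
from hypothesis import settings

from pms8 import DNA, Alphabet, generate_planted_instance

# deterministic property tests, no example database on disk
settings.register_profile("deterministic", database=None, derandomize=True)
settings.load_profile("deterministic")

TOY5 = Alphabet("toy5", "ABCDE")


@pytest.fixture(scope="session")
def small_planted():
    """An (l=7, d=2) planted instance small enough for every code path."""
    instance, record = generate_planted_instance(8, 50, 7, 2, seed=5)
    return instance, record


def random_tuple(rng: np.random.Generator, k: int, l: int, sigma: int = 4):
    """k random l-mer code rows."""
    return rng.integers(0, sigma, size=(k, l), dtype=np.uint8)


def decode_dna(codes) -> str:
    return DNA.decode(codes)
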