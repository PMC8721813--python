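import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from tsdscan import Background, SequenceRecord, default_element, simulate_genome


@pytest.fixture(scope="session")
def te():
    """The default 2.1 kb synthetic transposon with 30-bp TIRs."""
    return default_element()


@pytest.fixture(scope="session")
def small_genome():
    """100 kb uniform-composition genome, fixed seed."""
    return simulate_genome(100_000, Background.uniform(), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(2021)


def random_dna(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture()
def make_dna(rng):
    return lambda length: random_dna(rng, length)
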