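import random

import pytest

from ltrcraft import synth
from ltrcraft.seqio import PipelineConfig


@pytest.fixture(scope="session")
def small_library():
    """Two-superfamily reference library (Del/CRM Gypsy, Tork/SIRE Copia)."""
    return synth.make_reference_library(["Del", "CRM", "Tork", "SIRE"], seed=11)


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return random.Random(1234)


def random_nt(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def random_aa(rng, n):
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n))
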