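import numpy as np
import pytest

from bglbrick import synthdata
from bglbrick.seqcore import DnaSequence


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20110920)


@pytest.fixture()
def clean_seq_factory():
    """Deterministic factory for restriction-clean random sequences."""

    def make(length: int, seed: int, circular: bool = False) -> DnaSequence:
        r = np.random.default_rng(seed)
        return DnaSequence(synthdata.random_clean_seq(length, r), circular=circular)

    return make


@pytest.fixture()
def random_seq_factory():
    """Uniform random ACGT sequences (sites allowed)."""

    def make(length: int, seed: int, circular: bool = False) -> DnaSequence:
        r = np.random.default_rng(seed)
        bases = "".join(r.choice(np.array(list("ACGT")), size=length))
        return DnaSequence(bases, circular=circular)

    return make
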