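import numpy as np
import pytest

from fragilome.seqio import Genome
from fragilome.synthgen import markov_genome, random_genome, random_transition_matrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_30kb() -> Genome:
    """iid uniform 30 kb genome (near-maximal entropy)."""
    return random_genome(30_000, seed=101, id="rand30k")


@pytest.fixture(scope="session")
def markov_5kb() -> Genome:
    """Structured 5 kb genome from a biased second-order Markov model."""
    tm = random_transition_matrix(7)
    return markov_genome(5_000, tm, seed=17, id="markov5k")


@pytest.fixture()
def toy_genome() -> Genome:
    return Genome(id="toy", sequence="ACGTACGTAA")
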