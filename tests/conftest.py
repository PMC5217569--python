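import numpy as np
import pytest

from bsartifact.align import GenomeIndex
from bsartifact.genome import ReferenceGenome, index_cytosines, synthetic_genome


@pytest.fixture(scope="session")
def lambda_genome():
    return synthetic_genome()


@pytest.fixture(scope="session")
def lambda_index(lambda_genome):
    return index_cytosines(lambda_genome)


@pytest.fixture(scope="session")
def lambda_gindex(lambda_genome):
    return GenomeIndex(lambda_genome)


@pytest.fixture(scope="session")
def small_genome():
    """3 kb random genome for aligner oracle tests."""
    rng = np.random.default_rng(301)
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    return ReferenceGenome([("chrS", seq)])


@pytest.fixture(scope="session")
def small_index(small_genome):
    return index_cytosines(small_genome)


@pytest.fixture(scope="session")
def small_gindex(small_genome):
    return GenomeIndex(small_genome)
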