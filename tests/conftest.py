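import numpy as np
import pytest

from cisscout import GenomeSpec, make_genome
from cisscout.simgen import Genome


@pytest.fixture(scope="session")
def small_genome():
    """200 kb single-chromosome genome with sequence and motif index."""
    return make_genome(GenomeSpec(chromosomes=(("chr1", 200_000),), seed=11))


@pytest.fixture(scope="session")
def two_chrom_genome():
    return make_genome(GenomeSpec(chromosomes=(("chr1", 300_000), ("chr2", 200_000)), seed=23))


@pytest.fixture(scope="session")
def coord_genome_10mb():
    """Coordinate-only genome for insertion-level statistics."""
    return Genome.from_chrom_sizes({"chr1": 10_000_000})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
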