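import numpy as np
import pytest

from loxscan.io_core import LOXPSYM_SEQ
from loxscan.simulate import insert_lox, make_toy_genome, random_lox_spec


@pytest.fixture(scope="session")
def small_strain():
    """Two-chromosome 0.5 Mb genome with six lox loci (shared read-only)."""
    genome = make_toy_genome(2, [300_000, 200_000], seed=101)
    spec = random_lox_spec(genome, 6, min_per_chrom=2, seed=102)
    parent, sites = insert_lox(genome, spec)
    return parent, sites


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def lox():
    return LOXPSYM_SEQ
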