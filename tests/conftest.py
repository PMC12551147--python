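import numpy as np
import pytest

from teploop.descriptors import load_scales
from teploop.design import DesignContext
from teploop.sequence_space import AMINO_ACIDS, CodonUsageTable


@pytest.fixture(scope="session")
def scales():
    return load_scales()


@pytest.fixture(scope="session")
def codon_table():
    return CodonUsageTable.load()


#: Restricted design alphabet for fast campaign tests; contains the SKIK
#: residues plus D and N so the default landscape bonus applies.
SMALL_ALPHABET = "ADIKNS"


@pytest.fixture(scope="session")
def small_context(scales, codon_table):
    return DesignContext.build(
        alphabet=SMALL_ALPHABET, scales=scales, codon_table=codon_table
    )


@pytest.fixture(scope="session")
def full_context(scales, codon_table):
    """The complete 160,000-peptide feature matrix (built once per session)."""
    return DesignContext.build(scales=scales, codon_table=codon_table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peptides(rng, n, alphabet=AMINO_ACIDS, length=4):
    letters = list(alphabet)
    return [
        "".join(letters[i] for i in row)
        for row in rng.integers(0, len(letters), size=(n, length))
    ]
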