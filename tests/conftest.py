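import numpy as np
import pytest
from hypothesis import settings

from mitocohort.genome import Feature, GenomeMap
from mitocohort.haplotyping import Phylotree
from mitocohort.reference import synthetic_rcrs

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def gm() -> GenomeMap:
    return GenomeMap.default()


@pytest.fixture(scope="session")
def ref_seq() -> str:
    return synthetic_rcrs()


@pytest.fixture(scope="session")
def tree() -> Phylotree:
    return Phylotree.default()


@pytest.fixture()
def toy_genome():
    """A 30 bp toy genome with one heavy-strand and one light-strand
    protein gene, for hand-checkable effect prediction.

    Heavy gene (4-12): ATG GCC TAA.  Light gene (16-24): genome bases
    TTAGGCCAT, i.e. coding sequence ATGGCCTAA after reverse complement.
    """
    seq = "AAA" + "ATGGCCTAA" + "AAA" + "TTAGGCCAT" + "AAAAAA"
    gm = GenomeMap(
        features=[
            Feature("geneH", 4, 12, "H", "protein"),
            Feature("geneL", 16, 24, "L", "protein"),
        ],
        genome_length=len(seq),
    )
    return gm, seq
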