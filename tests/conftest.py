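import numpy as np
import pytest

from mitokit import datasets
from mitokit.codons import CodonUsageTable
from mitokit.rearrangement import GeneOrder, Token


@pytest.fixture(scope="session")
def omeimontis():
    """The published 40-feature annotation (20,120 bp circle)."""
    return datasets.rana_omeimontis_genome()


@pytest.fixture(scope="session")
def published_counts():
    return datasets.codon_counts()


@pytest.fixture(scope="session")
def usage_table(published_counts):
    return CodonUsageTable.from_counts(published_counts)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def abstract_order(spec: str, name: str = "") -> GeneOrder:
    """Build a gene order from abstract space-separated tokens ('-X' = L strand,
    'psX' = pseudogene); used for combinatorial tests that do not need the
    canonical mitochondrial alphabet."""
    toks = []
    for raw in spec.split():
        strand = "+"
        if raw.startswith("-"):
            strand, raw = "-", raw[1:]
        pseudo = raw.startswith("ps")
        if pseudo:
            raw = raw[2:]
        toks.append(Token(name=raw, strand=strand, pseudo=pseudo))
    return GeneOrder(tuple(toks), name=name)
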