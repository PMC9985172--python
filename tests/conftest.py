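import numpy as np
import pytest

from bryostruct.formats_io import GeneRecord


@pytest.fixture
def multi_exon_genes():
    """Hand-built genes with non-trivial exon/intron structure."""
    return [
        GeneRecord("gA", "s1", 0, 350, "+",
                   exons=((0, 100), (150, 350)), protein_length=100),
        GeneRecord("gB", "s1", 500, 800, "-",
                   exons=((500, 800),), protein_length=100),
        GeneRecord("gC", "s2", 10, 910, "+",
                   exons=((10, 310), (400, 700), (760, 910)),
                   protein_length=250),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20230202)


def make_gene(gene_id, scaffold, start, end, strand="+", protein_length=200,
              rank=None):
    return GeneRecord(gene_id, scaffold, start, end, strand,
                      exons=((start, end),), protein_length=protein_length,
                      rank=rank)


@pytest.fixture
def gene_factory():
    return make_gene
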