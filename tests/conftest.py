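import pytest

from oxgrid import simdata
from oxgrid.core import AnnotationSet, AssemblyLayout, GeneModel


def make_gene(gid, chrom, start, end, strand="+", source="sim", exons=None):
    return GeneModel(gid, chrom, start, end, strand, source, exons)


@pytest.fixture
def small_config():
    return simdata.SimConfig(
        n_chromosomes=2,
        chromosome_length=100_000,
        n_genes_per_chromosome=10,
        gene_length=(1_000, 2_000),
        seed=1,
    )


@pytest.fixture
def small_genome(small_config):
    return simdata.simulate_base_genome(small_config)


@pytest.fixture
def toy_layout():
    return AssemblyLayout([("chrA", 100_000), ("chrB", 100_000)])


@pytest.fixture
def toy_annotation(toy_layout):
    genes = [
        make_gene("gA1", "chrA", 1_000, 3_000, "+"),
        make_gene("gA2", "chrA", 10_000, 12_000, "-"),
        make_gene("gB1", "chrB", 5_000, 8_000, "+"),
    ]
    return AnnotationSet(toy_layout, genes)
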