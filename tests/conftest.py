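import pytest

from hackdesign.donor_design import LinkerConfig
from hackdesign.fixtures import ToyGenomeSpec, build_toy_genome
from hackdesign.genome_io import GeneModel, ReferenceGenome, revcomp

# 40-bp contig: 10 bp pad, a 12-bp CDS (ATG AAA CCC TAA), then GGGTTT
# and a 12-bp tail.  Junction of the plus-strand gene is at 22.
PLUS_CONTIG = "GATCGATCGA" + "ATGAAACCCTAA" + "GGGTTT" + "CATCATCATCAT"


@pytest.fixture
def plus_genome():
    return ReferenceGenome({"c1": PLUS_CONTIG})


@pytest.fixture
def plus_gene():
    return GeneModel(
        gene_id="gplus",
        contig="c1",
        strand="+",
        cds=((10, 22),),
        stop_codon=(19, 22),
        junction=22,
    )


@pytest.fixture
def minus_genome():
    return ReferenceGenome({"c1": revcomp(PLUS_CONTIG)})


@pytest.fixture
def minus_gene():
    # mirrored coordinates: [40-22, 40-10) on the reverse-complement contig
    return GeneModel(
        gene_id="gminus",
        contig="c1",
        strand="-",
        cds=((18, 30),),
        stop_codon=(18, 21),
        junction=18,
    )


@pytest.fixture
def linker():
    # 9-bp placeholder linker used throughout the worked examples
    return LinkerConfig(igg="GGGTTTAAA")


@pytest.fixture(scope="session")
def toy20():
    """Session-wide 20-gene toy genome, every gene with a valid guide."""
    return build_toy_genome(ToyGenomeSpec(n_genes=20, seed=1))
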