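import numpy as np
import pytest

from hackdesign.donor_design import build_cassette, derive_primers
from hackdesign.edit_sim import (
    in_silico_pcr,
    integrate,
    recut_check,
)
from hackdesign.errors import (
    AmbiguousProductError,
    DesignError,
    NoAmpliconError,
)
from hackdesign.fixtures import ToyGenomeSpec, build_toy_genome
from hackdesign.genome_io import ReferenceGenome, revcomp, translate
from hackdesign.guide_design import GuideHit, annotate_matches, filter_guides, scan_protospacers

from conftest import PLUS_CONTIG
from helpers import splice_insert

GOI = "ATGGCTTAA"


@pytest.fixture
def pathway_cassette(plus_genome, plus_gene, linker):
    return build_cassette(plus_gene, plus_genome, GOI, linker, arm_up=6, arm_down=6)


class TestIntegrate:
    def test_plus_strand_matches_string_splice_oracle(
        self, plus_genome, plus_gene, pathway_cassette
    ):
        edited = integrate(plus_genome, plus_gene, pathway_cassette)
        insert = "GGGTTTAAA" + "ATGGCT" + "TAA"
        assert edited.edited_sequence == splice_insert(PLUS_CONTIG, 22, insert, "+")
        assert "CCCTAA" + insert + "GGGTTT" in edited.edited_sequence
        a, b = edited.insert_interval
        assert edited.edited_sequence[a:b] == insert
        assert edited.proteins == ("MKP", "MA")

    def test_minus_strand_insert_is_revcomp_at_junction(
        self, minus_genome, minus_gene, linker
    ):
        cassette = build_cassette(minus_gene, minus_genome, GOI, linker, arm_up=6, arm_down=6)
        edited = integrate(minus_genome, minus_gene, cassette)
        insert = "GGGTTTAAA" + "ATGGCT" + "TAA"
        expected = splice_insert(revcomp(PLUS_CONTIG), 18, insert, "-")
        assert edited.edited_sequence == expected
        a, b = edited.insert_interval
        assert edited.edited_sequence[a:b] == revcomp(insert)
        assert edited.proteins == ("MKP", "MA")

    def test_arm_mismatch_quotes_offset(self, plus_genome, plus_gene, pathway_cassette):
        mutated = ReferenceGenome(
            {"c1": PLUS_CONTIG[:17] + "G" + PLUS_CONTIG[18:]}  # CCCTAA -> CGCTAA
        )
        with pytest.raises(DesignError, match="offset 1"):
            integrate(mutated, plus_gene, pathway_cassette)

    def test_delete_downstream_removes_utr_prefix(self, toy20, linker):
        gene = next(m for m in toy20.models if m.strand == "+")
        c = build_cassette(gene, toy20.genome, GOI, linker,
                           arm_up=20, arm_down=20, delete_downstream=45)
        edited = integrate(toy20.genome, gene, c)
        seq = toy20.genome.sequences[gene.contig]
        insert = "GGGTTTAAA" + "ATGGCT" + "TAA"
        expected = seq[: gene.junction] + insert + seq[gene.junction + 45 :]
        assert edited.edited_sequence == expected

    def test_splice_then_delete_restores_genome(self, toy20, linker):
        for gene in toy20.models:
            c = build_cassette(gene, toy20.genome, GOI, linker)
            edited = integrate(toy20.genome, gene, c)
            a, b = edited.insert_interval
            restored = edited.edited_sequence[:a] + edited.edited_sequence[b:]
            assert restored == toy20.genome.sequences[gene.contig]

    def test_driver_protein_conserved(self, toy20, linker):
        for gene in toy20.models:
            wild = translate(gene.spliced_cds(toy20.genome))[:-1]
            c = build_cassette(gene, toy20.genome, GOI, linker)
            edited = integrate(toy20.genome, gene, c)
            assert edited.proteins[0] == wild

    def test_library_mode_appends_flag_to_driver(self, toy20, linker):
        gene = toy20.models[0]
        wild = translate(gene.spliced_cds(toy20.genome))[:-1]
        c = build_cassette(gene, toy20.genome, GOI, linker, mode="library")
        edited = integrate(toy20.genome, gene, c)
        assert edited.proteins[0] == wild + "DYKDDDDK"

    def test_bicistron_yields_exactly_two_orfs(self, toy20, linker):
        gene = toy20.models[1]
        c = build_cassette(gene, toy20.genome, GOI, linker)
        edited = integrate(toy20.genome, gene, c)
        cds = edited.bicistron_cds
        # ORF1 ends at the driver stop, ORF2 at the goi stop, nothing after
        assert cds.endswith("TAA")
        assert len(edited.proteins) == 2
        protein2 = edited.proteins[1]
        assert "*" not in protein2

    def test_wrong_gene_for_cassette_is_error(self, toy20, plus_gene, linker):
        c = build_cassette(toy20.models[0], toy20.genome, GOI, linker)
        with pytest.raises(DesignError, match="gplus"):
            integrate(toy20.genome, plus_gene, c)


class TestRecutCheck:
    def _design(self, toy, gene, linker):
        c = build_cassette(gene, toy.genome, GOI, linker)
        hits = filter_guides(annotate_matches(toy.genome, scan_protospacers(toy.genome, gene)))
        return integrate(toy.genome, gene, c), hits[0]

    def test_guide_cutting_at_junction_is_disrupted(self, toy20, linker):
        for gene in toy20.models[:8]:
            edited, guide = self._design(toy20, gene, linker)
            assert recut_check(edited, guide) == "disrupted"

    def test_distant_spacer_survives_insertion(self, linker):
        # a guide whose full spacer+PAM lies >=23 bp upstream of the
        # junction remains intact after insertion at the junction
        from hackdesign.genome_io import GeneModel

        spacer = "ATCGATCATCGATCGATACG"
        seq = spacer + "AGG" + "ATCATCATCATCATCATCAT" + "ATGAAACCCTAA" + "GTTGTTGTTGTT"
        genome = ReferenceGenome({"c1": seq})
        junction = len(spacer) + 3 + 20 + 12
        gene = GeneModel("g", "c1", "+", ((junction - 12, junction),),
                         (junction - 3, junction), junction)
        c = build_cassette(gene, genome, GOI, linker, arm_up=6, arm_down=6)
        edited = integrate(genome, gene, c)
        guide = GuideHit("g", spacer, "AGG", "+", 17, junction - 17, 0.5, 1)
        assert recut_check(edited, guide, flank=len(seq)) == "intact"

    def test_agrees_with_full_sequence_scan(self, linker):
        toy = build_toy_genome(ToyGenomeSpec(n_genes=8, seed=3))
        for gene in toy.models:
            edited, guide = self._design(toy, gene, linker)
            full = edited.edited_sequence
            from helpers import brute_force_match_count

            n = brute_force_match_count([full], guide.spacer)
            verdict = recut_check(edited, guide, flank=len(full))
            assert verdict == ("intact" if n else "disrupted")


class TestInSilicoPCR:
    def test_reconstructs_donor_from_embedded_template(
        self, pathway_cassette, plus_genome, plus_gene, linker
    ):
        rng = np.random.default_rng(11)
        ctx1 = "".join(rng.choice(list("ACGT"), size=200))
        ctx2 = "".join(rng.choice(list("ACGT"), size=200))
        template = ctx1 + pathway_cassette.full_sequence + ctx2
        p = derive_primers(pathway_cassette, anneal_len=6)
        amp = in_silico_pcr(template, p.fwd, p.rev, min_anneal=6)
        assert amp.sequence == pathway_cassette.full_sequence
        assert amp.length == len(pathway_cassette.full_sequence)
        assert amp.fwd_site <= amp.rev_site

    def test_mismatched_3prime_base_no_amplicon(self):
        template = "A" * 30 + "ATCGATCGATCGATCGATCG" + "T" * 30
        fwd_bad = "ATCGATCGATCGATCGATCC"
        rev = revcomp(template[-25:])
        with pytest.raises(NoAmpliconError):
            in_silico_pcr(template, fwd_bad, rev, min_anneal=18)

    def test_duplicate_forward_site_is_ambiguous(self):
        site = "ATCGATCGATCGATCGATCG"
        template = site + "AAAA" + site + "CCCCGGGGTTTTACGTACGTACGT"
        rev = revcomp(template[-20:])
        with pytest.raises(AmbiguousProductError):
            in_silico_pcr(template, site, rev, min_anneal=20)

    def test_wrong_orientation_no_amplicon(self):
        template = "ACGTACGTACGTACGTACGTAAACCCTTTGGGATCGATCGATCGATCGATCG"
        fwd = template[-20:]
        rev = revcomp(template[:20])
        with pytest.raises(NoAmpliconError, match="orientation"):
            in_silico_pcr(template, fwd, rev, min_anneal=20)
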