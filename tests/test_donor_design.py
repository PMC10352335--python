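import io

import numpy as np
import pytest
from Bio import SeqIO

from hackdesign.donor_design import (
    DonorCassette,
    LinkerConfig,
    build_cassette,
    cassette_to_seqrecord,
    derive_primers,
    validate_cassette,
)
from hackdesign.edit_sim import in_silico_pcr
from hackdesign.errors import DesignError
from hackdesign.genome_io import revcomp, translate

GOI = "ATGGCTTAA"  # Met-Ala-stop


class TestBuildCassette:
    def test_pathway_parts_and_concatenation(self, plus_genome, plus_gene, linker):
        c = build_cassette(
            plus_gene, plus_genome, GOI, linker, mode="pathway", arm_up=6, arm_down=6
        )
        assert [n for n, _ in c.parts] == ["UpTA", "IGG", "GOI", "goi_stop", "DownTA"]
        assert c.full_sequence == "CCCTAA" + "GGGTTTAAA" + "ATGGCT" + "TAA" + "GGGTTT"

    def test_goi_terminal_stop_stripped_then_readded(self, plus_genome, plus_gene, linker):
        with_stop = build_cassette(plus_gene, plus_genome, GOI, linker, arm_up=6, arm_down=6)
        without = build_cassette(plus_gene, plus_genome, GOI[:-3], linker, arm_up=6, arm_down=6)
        assert with_stop.full_sequence == without.full_sequence

    def test_localization_tag_translation(self, plus_genome, plus_gene):
        cfg = LinkerConfig(igg="GGGTTTAAA", localization_tag="TCTAAATTG")  # SKL
        c = build_cassette(plus_gene, plus_genome, GOI, cfg, arm_up=6, arm_down=6)
        names = [n for n, _ in c.parts]
        assert names == ["UpTA", "IGG", "GOI", "tag", "goi_stop", "DownTA"]
        insert_protein = translate(c.part("GOI") + c.part("tag"))
        assert insert_protein == "MASKL"

    def test_library_mode_flag_before_driver_stop(self, plus_genome, plus_gene, linker):
        # driver's last codons are ...CCC TAA: arm ends at CCC, then FLAG, then TAA
        c = build_cassette(
            plus_gene, plus_genome, GOI, linker, mode="library", arm_up=6, arm_down=6
        )
        names = [n for n, _ in c.parts]
        assert names == ["UpTA", "FLAG", "driver_stop", "IGG", "GOI", "goi_stop", "DownTA"]
        assert c.part("UpTA").endswith("CCC")
        assert c.part("driver_stop") == "TAA"
        # UpTA tail + FLAG reads in frame as Pro + DYKDDDDK
        assert translate(c.part("UpTA")[-3:] + c.part("FLAG")) == "PDYKDDDDK"

    def test_default_arm_lengths_by_mode(self, toy20):
        m = toy20.models[0]
        lib = build_cassette(m, toy20.genome, GOI, mode="library")
        pw = build_cassette(m, toy20.genome, GOI, mode="pathway")
        assert (lib.arm_up_len, lib.arm_down_len) == (40, 40)
        assert (pw.arm_up_len, pw.arm_down_len) == (60, 60)

    def test_goi_internal_stop_names_codon(self, plus_genome, plus_gene, linker):
        with pytest.raises(DesignError, match="codon 2"):
            build_cassette(
                plus_gene, plus_genome, "ATGGCTTGAGCTTAA", linker, arm_up=6, arm_down=6
            )

    def test_goi_without_atg_rejected(self, plus_genome, plus_gene, linker):
        with pytest.raises(DesignError, match="ATG"):
            build_cassette(plus_gene, plus_genome, "GCTGCTTAA", linker, arm_up=6, arm_down=6)

    def test_frame_breaking_tag_rejected(self):
        with pytest.raises(DesignError, match="divisible by 3"):
            LinkerConfig(localization_tag="TCTAAATT")


class TestDerivePrimers:
    def test_primer_composition_example(self, plus_genome, plus_gene, linker):
        c = build_cassette(plus_gene, plus_genome, GOI, linker, arm_up=6, arm_down=6)
        p = derive_primers(c, anneal_len=6)
        assert p.fwd == "CCCTAA" + "GGGTTTAAA" + "ATGGCT"
        assert p.rev == revcomp("ATGGCT" + "TAA" + "GGGTTT")

    def test_library_primer_carries_flag_and_stop(self, plus_genome, plus_gene, linker):
        c = build_cassette(plus_gene, plus_genome, GOI, linker, mode="library",
                           arm_up=6, arm_down=6)
        p = derive_primers(c, anneal_len=6)
        assert p.fwd == c.part("UpTA") + c.part("FLAG") + "TAA" + "GGGTTTAAA" + "ATGGCT"

    def test_anneal_longer_than_goi_is_error(self, plus_genome, plus_gene, linker):
        c = build_cassette(plus_gene, plus_genome, GOI, linker, arm_up=6, arm_down=6)
        with pytest.raises(DesignError, match="anneal"):
            derive_primers(c, anneal_len=7)

    def test_long_primer_warns(self, toy20, linker):
        m = toy20.models[0]
        c = build_cassette(m, toy20.genome, "ATG" + "GAAGCT" * 20 + "TAA", linker,
                           arm_up=95, arm_down=60)
        with pytest.warns(UserWarning, match="synthesis may be impractical"):
            derive_primers(c, anneal_len=20)

    @pytest.mark.parametrize("seed", range(20))
    def test_pcr_on_bare_goi_reconstructs_donor(self, toy20, linker, seed):
        # the module's key cross-check: amplifying the bare GOI with the
        # derived primers rebuilds the donor exactly
        rng = np.random.default_rng(seed)
        n_codons = int(rng.integers(30, 200))
        goi = "ATG" + "".join(
            c for c in ["".join(rng.choice(list("ACGT"), size=3))
                        for _ in range(n_codons)]
            if c not in ("TAA", "TAG", "TGA")
        )
        gene = toy20.models[seed % len(toy20.models)]
        c = build_cassette(gene, toy20.genome, goi, linker)
        p = derive_primers(c)
        amp = in_silico_pcr(goi, p.fwd, p.rev)
        assert amp.sequence == c.full_sequence


class TestValidateCassette:
    def test_well_formed_cassette_passes(self, plus_genome, plus_gene, linker):
        c = build_cassette(plus_gene, plus_genome, GOI, linker, arm_up=6, arm_down=6)
        report = validate_cassette(c, linker)
        assert report.ok, report.failures

    def test_igg_duplicated_by_pathological_goi(self, plus_genome, plus_gene, linker):
        # GOI carrying the IGG string itself (length stays a codon multiple)
        goi = "ATG" + "GGGTTTAAA" + "TAA"
        c = build_cassette(plus_gene, plus_genome, goi, linker, arm_up=6, arm_down=6)
        report = validate_cassette(c, linker)
        assert not report.ok
        assert any(f.name == "igg_single_copy" for f in report.failures)

    def test_internal_stop_in_goi_part_fails_orf_check(self, linker):
        c = DonorCassette(
            gene_id="g", mode="pathway",
            parts=(("UpTA", "CCCTAA"), ("IGG", linker.igg),
                   ("GOI", "ATGTGAGCT"), ("goi_stop", "TAA"), ("DownTA", "GGGTTT")),
            arm_up_len=6, arm_down_len=6)
        report = validate_cassette(c, linker)
        fails = {f.name: f.detail for f in report.failures}
        assert "goi_orf_intact" in fails and "codon 1" in fails["goi_orf_intact"]

    def test_part_order_grammar_violation_detected(self, linker):
        c = DonorCassette(
            gene_id="g", mode="pathway",
            parts=(("IGG", linker.igg), ("UpTA", "CCCTAA"),
                   ("GOI", "ATGGCT"), ("goi_stop", "TAA"), ("DownTA", "GGGTTT")),
            arm_up_len=6, arm_down_len=6)
        assert any(f.name == "part_order" for f in validate_cassette(c, linker).failures)

    def test_genbank_round_trip_preserves_part_boundaries(self, plus_genome, plus_gene, linker):
        c = build_cassette(plus_gene, plus_genome, GOI, linker, arm_up=6, arm_down=6)
        buf = io.StringIO()
        SeqIO.write(cassette_to_seqrecord(c), buf, "genbank")
        buf.seek(0)
        rec = SeqIO.read(buf, "genbank")
        assert str(rec.seq) == c.full_sequence
        labels = [(f.qualifiers["label"][0], int(f.location.start), int(f.location.end))
                  for f in rec.features]
        pos, expected = 0, []
        for name, seq in c.parts:
            expected.append((name, pos, pos + len(seq)))
            pos += len(seq)
        assert labels == expected
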