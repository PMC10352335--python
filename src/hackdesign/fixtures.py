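"""Synthetic genomes, annotations and abundance tables for offline use.

The toy generator emulates the real use case (a yeast genome plus a
proteomic abundance table) at desk scale: intronless protein-coding
genes on one contig, each with an 80-bp flank on both sides, random
strand, and a lognormal abundance.  For a configurable fraction of
genes an NGG PAM is planted just downstream of the stop codon so that
a guide passing the default filters (cut within 5 bp of the junction,
GC and TTTT hygiene, genome-unique) exists; for the remaining genes
the whole locus is synthesized free of GG/CC dinucleotides so that no
SpCas9 site can fall near the junction at all.  Output is fully
determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .donor_design import MDH3_TAG, LinkerConfig
from .errors import DesignError
from .genome_io import (
    STOP_CODONS,
    GeneModel,
    ReferenceGenome,
    revcomp,
    write_genome,
    write_gff3,
)
from .guide_design import annotate_matches, filter_guides, scan_protospacers

BASES = "ACGT"
FLANK_PAD = 80
GAP = 60
_MAX_BLOCK_TRIES = 200


@dataclass(frozen=True)
class ToyGenomeSpec:
    """Parameters of a synthetic test genome; the seed fixes everything."""

    n_genes: int = 20
    seed: int = 1
    frac_with_valid_guide: float = 1.0
    cds_len_range: tuple[int, int] = (100, 300)  # codons incl. start/stop
    abundance_lognormal: tuple[float, float] = (14.0, 1.5)
    contig_len: int | None = None  # None: exactly as large as needed

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.frac_with_valid_guide <= 1.0:
            raise ValueError("frac_with_valid_guide must be in [0, 1]")
        if self.cds_len_range[0] < 10 or self.cds_len_range[0] > self.cds_len_range[1]:
            raise ValueError("cds_len_range must be (min, max) with min >= 10")


@dataclass
class ToyGenome:
    genome: ReferenceGenome
    models: list[GeneModel]
    abundance: pd.DataFrame  # columns: protein_id, gene_id, abundance


@dataclass
class _Block:
    gene_id: str
    seq: str  # gene orientation
    cds_start: int  # local, gene orientation
    cds_end: int
    strand: str
    planted: bool


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random sense (non-stop) codons."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _pam_free_dna(rng: np.random.Generator, n: int, prev: str = "") -> str:
    """Random DNA with no GG or CC dinucleotide (so no NGG/CCN site)."""
    out: list[str] = []
    last = prev[-1:] if prev else ""
    for _ in range(n):
        allowed = [b for b in BASES if not (b == last and b in "GC")]
        b = str(rng.choice(allowed))
        out.append(b)
        last = b
    return "".join(out)


def _pam_free_codons(rng: np.random.Generator, n: int, prev: str) -> str:
    """n sense codons with no GG/CC within or across codon boundaries."""
    out: list[str] = []
    last = prev[-1:]
    while len(out) < n:
        codon = _pam_free_dna(rng, 3, last)
        if codon in STOP_CODONS:
            continue
        out.append(codon)
        last = codon[-1]
    return "".join(out)


def _make_block(
    rng: np.random.Generator, gene_id: str, n_codons: int, planted: bool
) -> _Block:
    """One gene locus in gene orientation, flanked by FLANK_PAD on each side."""
    strand = "+" if rng.random() < 0.5 else "-"
    if planted:
        up = _random_dna(rng, FLANK_PAD)
        cds = "ATG" + _random_codons(rng, n_codons - 2) + "TAA"
        down = list(_random_dna(rng, FLANK_PAD))
        # plus-orientation PAM 2 bp after the junction: cut lands 1 bp
        # inside the CDS, within the 5-bp design bound
        down[2:5] = "AGG"
        down = "".join(down)
        seq = up + cds + down
        jl = FLANK_PAD + len(cds)
        spacer = seq[jl - 18 : jl + 2]
        gc = (spacer.count("G") + spacer.count("C")) / len(spacer)
        if "TTTT" in spacer or not 0.2 <= gc <= 0.8:
            raise _RetryBlock
    else:
        up = _pam_free_dna(rng, FLANK_PAD)
        start = "ATG"  # contains neither GG nor CC
        body = _pam_free_codons(rng, n_codons - 2, prev=up + start)
        cds = start + body + "TAA"
        down = _pam_free_dna(rng, FLANK_PAD, prev=cds)
        if "GG" in cds[:4] or "CC" in cds[:4]:  # boundary with up pad
            raise _RetryBlock
        seq = up + cds + down
    return _Block(
        gene_id=gene_id,
        seq=seq,
        cds_start=FLANK_PAD,
        cds_end=FLANK_PAD + len(cds),
        strand=strand,
        planted=planted,
    )


class _RetryBlock(Exception):
    pass


def _assemble(blocks: list[_Block], rng: np.random.Generator, contig_len):
    pieces: list[str] = []
    models: list[GeneModel] = []
    pos = 0
    lead = _random_dna(rng, GAP)
    pieces.append(lead)
    pos += GAP
    for b in blocks:
        placed = b.seq if b.strand == "+" else revcomp(b.seq)
        blen = len(b.seq)
        if b.strand == "+":
            s, e = pos + b.cds_start, pos + b.cds_end
            stop = (e - 3, e)
            junction = e
        else:
            s = pos + blen - b.cds_end
            e = pos + blen - b.cds_start
            stop = (s, s + 3)
            junction = s
        models.append(
            GeneModel(
                gene_id=b.gene_id,
                contig="toy1",
                strand=b.strand,
                cds=((s, e),),
                stop_codon=stop,
                junction=junction,
            )
        )
        pieces.append(placed)
        pos += blen
        gap = _random_dna(rng, GAP)
        pieces.append(gap)
        pos += GAP
    seq = "".join(pieces)
    if contig_len is not None:
        if contig_len < len(seq):
            raise DesignError(
                f"contig_len {contig_len} too small: {len(seq)} bp needed "
                f"for {len(blocks)} genes"
            )
        seq += _random_dna(rng, contig_len - len(seq))
    return ReferenceGenome({"toy1": seq}), models


def build_toy_genome(spec: ToyGenomeSpec) -> ToyGenome:
    """In-memory toy genome; see module docstring for what it emulates.

    After assembly, every gene is verified with the guide scanner
    itself: planted genes must yield at least one guide passing the
    default filters and PAM-suppressed genes must yield none.  In the
    (vanishingly rare) event a planted spacer collides with sequence
    elsewhere, the offending locus is resynthesized.
    """
    rng = np.random.default_rng(spec.seed)
    n_planted = int(round(spec.frac_with_valid_guide * spec.n_genes))
    planted_idx = set(rng.permutation(spec.n_genes)[:n_planted].tolist())
    lo_c, hi_c = spec.cds_len_range

    def new_block(i: int) -> _Block:
        n_codons = int(rng.integers(lo_c, hi_c + 1))
        for _ in range(_MAX_BLOCK_TRIES):
            try:
                return _make_block(rng, f"g{i + 1:03d}", n_codons, i in planted_idx)
            except _RetryBlock:
                continue
        raise DesignError(f"could not synthesize locus g{i + 1:03d}")

    blocks = [new_block(i) for i in range(spec.n_genes)]
    for _ in range(5):
        genome, models = _assemble(blocks, rng, spec.contig_len)
        bad: list[int] = []
        for i, m in enumerate(models):
            hits = filter_guides(
                annotate_matches(genome, scan_protospacers(genome, m))
            )
            if blocks[i].planted and not hits:
                bad.append(i)
            elif not blocks[i].planted and hits:
                bad.append(i)
        if not bad:
            break
        for i in bad:
            blocks[i] = new_block(i)
    else:
        raise DesignError("toy genome failed guide verification after retries")

    mu, sigma = spec.abundance_lognormal
    abundances = rng.lognormal(mean=mu, sigma=sigma, size=spec.n_genes)
    table = pd.DataFrame(
        {
            "protein_id": [m.gene_id + "p" for m in models],
            "gene_id": [m.gene_id for m in models],
            "abundance": abundances,
        }
    )
    return ToyGenome(genome=genome, models=models, abundance=table)


def make_toy_genome(
    spec: ToyGenomeSpec, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write the toy genome as FASTA + GFF3 + abundance TSV; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    toy = build_toy_genome(spec)
    fasta = out_dir / "toy_genome.fa"
    gff = out_dir / "toy_genes.gff3"
    tsv = out_dir / "toy_abundance.tsv"
    write_genome(toy.genome, fasta)
    write_gff3(toy.models, gff)
    toy.abundance.to_csv(tsv, sep="\t", index=False)
    return fasta, gff, tsv


# --- packaged demo pathway configuration ---------------------------------

SQUALENE_MODULE = (
    "EfmvaE",
    "EfmvaS",
    "ERG8",
    "ERG9",
    "ERG12",
    "ERG19",
    "ERG20",
    "IDI1",
)
MOGROL_MODULE = ("AtCPR", "SgCYP87D18", "SgCDS", "SgSQE1", "SgEPH3")

#: Representative monocistronic driver abundances per tier (iBAQ-like
#: units, all above the 5e5 driver threshold).
TIER_ABUNDANCE = {"high": 5.0e6, "medium": 1.2e6, "low": 6.0e5}

_DEMO_SEED = 20230717
_DEMO_CDS_CODONS = 300


@dataclass(frozen=True)
class DemoConfig:
    """Packaged demo: a squalene (MVA) module plus a mogrol module.

    The coding sequences are synthetic placeholders generated from a
    fixed seed, not the real genes; they satisfy every donor-design
    precondition (ATG start, in frame, stop-free) so the full pipeline
    runs offline.  ``tier_variants`` emulates three strain designs that
    map three mogrol-module genes to drivers of decreasing strength.
    """

    squalene_genes: tuple[str, ...] = SQUALENE_MODULE
    mogrol_genes: tuple[str, ...] = MOGROL_MODULE
    goi_cds: dict = field(default_factory=dict)
    mode: str = "pathway"
    arm_up: int = 60
    arm_down: int = 60
    linker: LinkerConfig = field(
        default_factory=lambda: LinkerConfig(localization_tag=MDH3_TAG)
    )
    capacity: int = 4
    tier_variants: dict = field(default_factory=dict)
    tier_abundance: dict = field(default_factory=lambda: dict(TIER_ABUNDANCE))

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.squalene_genes + self.mogrol_genes

    def variant_tier(self, variant: str, gene: str) -> str:
        """Driver tier of a mogrol-module gene under a strain variant."""
        return self.tier_variants.get(variant, {}).get(gene, "high")

    def predicted_module_level(self, variant: str, eta=0.55, rho=0.50) -> float:
        """Summed predicted GOI level over the mogrol module."""
        return sum(
            eta * rho * self.tier_abundance[self.variant_tier(variant, g)]
            for g in self.mogrol_genes
        )


def demo_pathway_config() -> DemoConfig:
    """The packaged 13-gene demo configuration (8 MVA + 5 mogrol genes).

    Pathway mode with 60-bp arms and the peroxisomal localization tag
    on the reverse primer, matching multiplexed pathway construction;
    variant tier maps emulate high/medium/low driver choices for the
    three tunable mogrol genes.
    """
    rng = np.random.default_rng(_DEMO_SEED)
    cds = {
        name: "ATG" + _random_codons(rng, _DEMO_CDS_CODONS - 2)
        for name in SQUALENE_MODULE + MOGROL_MODULE
    }
    tunable = ("SgCDS", "SgSQE1", "SgEPH3")
    variants = {
        "HCM1": {g: "high" for g in tunable},
        "HCM2": {g: "medium" for g in tunable},
        "HCM3": {g: "low" for g in tunable},
    }
    return DemoConfig(goi_cds=cds, tier_variants=variants)
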