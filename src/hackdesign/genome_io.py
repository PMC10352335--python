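"""Genome/annotation I/O and strand-aware gene models.

All coordinates inside the package are 0-based half-open on the plus
strand of a contig.  GFF3 (1-based, fully closed) is converted at the
boundary, in both directions.  A :class:`GeneModel` records where a
gene's coding sequence ends: the ``junction`` is the between-base
coordinate immediately 3' of the stop codon in gene orientation, i.e.
the position at which a bicistronic insert is placed and from which
homology arms are measured.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    AmbiguousSequenceError,
    AnnotationError,
    DuplicateIdError,
    FlankError,
    GenomeError,
)

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    """Translate with the standard nuclear code; '*' marks stops."""
    return str(Seq(cds).translate())


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class ReferenceGenome:
    """Uppercase DNA sequences keyed by unique contig id."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.sequences.items():
            if not seq:
                raise GenomeError(f"contig {cid!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                pos = next(i for i, b in enumerate(seq) if b in bad)
                raise GenomeError(
                    f"contig {cid!r} has non-IUPAC character "
                    f"{seq[pos]!r} at position {pos}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(s) for cid, s in self.sequences.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with stop-codon and junction coordinates.

    ``cds`` lists genomic intervals in ascending genomic order
    regardless of strand; the spliced CDS of a minus-strand gene is the
    reverse complement of their concatenation.  ``junction`` is the
    plus-strand between-base coordinate immediately downstream (in gene
    orientation) of the stop codon's last base.
    """

    gene_id: str
    contig: str
    strand: str
    cds: tuple[tuple[int, int], ...]
    stop_codon: tuple[int, int]
    junction: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        s, e = self.stop_codon
        if e - s != 3:
            raise AnnotationError(f"{self.gene_id}: stop codon is not 3 bp")
        expected = e if self.strand == "+" else s
        if self.junction != expected:
            raise AnnotationError(
                f"{self.gene_id}: junction {self.junction} inconsistent "
                f"with stop codon {self.stop_codon} on strand {self.strand}"
            )

    def spliced_cds(self, genome: ReferenceGenome) -> str:
        """Spliced CDS 5'->3' in gene orientation (includes the stop)."""
        seq = genome.sequences[self.contig]
        joined = "".join(seq[s:e] for s, e in self.cds)
        return joined if self.strand == "+" else revcomp(joined)


class ModelList(list):
    """List of accepted GeneModels; ``excluded`` holds (gene_id, reason)."""

    def __init__(self, models=(), excluded=()):
        super().__init__(models)
        self.excluded: list[tuple[str, str]] = list(excluded)


def read_genome(path: str | Path) -> ReferenceGenome:
    """Parse a FASTA file into a validated :class:`ReferenceGenome`.

    Sequences are uppercased; N is allowed.  Duplicate contig ids and
    non-IUPAC characters are hard errors.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise DuplicateIdError(f"duplicate contig id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise GenomeError(f"contig {rec.id!r} in {path} is empty")
        sequences[rec.id] = seq
    if not sequences:
        raise GenomeError(f"no FASTA records found in {path}")
    return ReferenceGenome(sequences)


def write_genome(genome: ReferenceGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.sequences.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _validate_gene(
    gene_id: str,
    contig: str,
    strand: str,
    intervals: list[tuple[int, int]],
    genome: ReferenceGenome,
) -> GeneModel:
    """Build a GeneModel or raise AnnotationError with the reason."""
    if contig not in genome:
        # unknown contig is a hard error at the caller level
        raise KeyError(contig)
    clen = genome.lengths[contig]
    if not intervals:
        raise AnnotationError("no CDS features")
    intervals = sorted(intervals)
    for s, e in intervals:
        if s < 0 or e > clen:
            raise AnnotationError(f"CDS [{s},{e}) outside contig of length {clen}")
        if e <= s:
            raise AnnotationError(f"empty CDS interval [{s},{e})")
    total = sum(e - s for s, e in intervals)
    if total % 3:
        raise AnnotationError(f"CDS length {total} not divisible by 3")
    seq = genome.sequences[contig]
    spliced = "".join(seq[s:e] for s, e in intervals)
    if strand == "-":
        spliced = revcomp(spliced)
    if not spliced.startswith("ATG"):
        raise AnnotationError("spliced CDS does not begin with ATG")
    if spliced[-3:] not in STOP_CODONS:
        raise AnnotationError(f"spliced CDS ends with {spliced[-3:]!r}, not a stop")
    internal = [
        i for i in range(0, len(spliced) - 3, 3) if spliced[i : i + 3] in STOP_CODONS
    ]
    if internal:
        raise AnnotationError(f"internal stop codon at codon {internal[0] // 3}")
    if strand == "+":
        last = intervals[-1]
        stop = (last[1] - 3, last[1])
        junction = last[1]
        if stop[0] < last[0]:
            raise AnnotationError("stop codon not contained in last CDS interval")
    else:
        first = intervals[0]
        stop = (first[0], first[0] + 3)
        junction = first[0]
        if stop[1] > first[1]:
            raise AnnotationError("stop codon not contained in last CDS interval")
    return GeneModel(
        gene_id=gene_id,
        contig=contig,
        strand=strand,
        cds=tuple(intervals),
        stop_codon=stop,
        junction=junction,
    )


def read_annotation(
    path: str | Path,
    genome: ReferenceGenome,
    isoform: str = "first",
) -> ModelList:
    """Read gene/mRNA/CDS features from GFF3 into validated GeneModels.

    One model per gene: the first mRNA in file order wins by default;
    ``isoform='longest_cds'`` selects the transcript with the longest
    spliced CDS instead.  Models that violate CDS invariants (frame,
    start/stop codons, contig bounds) are excluded, not fatal; the
    returned :class:`ModelList` carries ``(gene_id, reason)`` pairs in
    ``.excluded``.  A feature on an unknown contig is a hard error.
    """
    if isoform not in ("first", "longest_cds"):
        raise ValueError(f"isoform must be 'first' or 'longest_cds', got {isoform!r}")
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    excluded: list[tuple[str, str]] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in genome:
            raise AnnotationError(
                f"gene {gene.id!r} on unknown contig {gene.seqid!r}"
            )
        mrnas = list(db.children(gene, featuretype="mRNA", level=1))
        if mrnas:
            choices = []
            for m in mrnas:
                ivs = [
                    (c.start - 1, c.end)
                    for c in db.children(m, featuretype="CDS")
                ]
                choices.append((m, ivs))
            if isoform == "longest_cds":
                choices.sort(key=lambda t: -sum(e - s for s, e in t[1]))
            intervals = choices[0][1]
        else:
            intervals = [
                (c.start - 1, c.end)
                for c in db.children(gene, featuretype="CDS")
            ]
        try:
            model = _validate_gene(
                gene.id, gene.seqid, gene.strand, intervals, genome
            )
        except KeyError:
            raise AnnotationError(
                f"gene {gene.id!r} on unknown contig {gene.seqid!r}"
            )
        except AnnotationError as exc:
            log.warning("excluding gene %s: %s", gene.id, exc)
            excluded.append((gene.id, str(exc)))
            continue
        models.append(model)
    if excluded:
        log.info("excluded %d of %d genes", len(excluded), len(excluded) + len(models))
    return ModelList(models, excluded)


def write_gff3(models: list[GeneModel], path: str | Path, source: str = "hackdesign") -> None:
    """Write gene/mRNA/CDS features (1-based inclusive) for each model."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo = min(s for s, _ in m.cds)
            hi = max(e for _, e in m.cds)
            attrs = f"ID={m.gene_id}"
            fh.write(
                f"{m.contig}\t{source}\tgene\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            mid = f"{m.gene_id}.t1"
            fh.write(
                f"{m.contig}\t{source}\tmRNA\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={mid};Parent={m.gene_id}\n"
            )
            for s, e in m.cds:
                fh.write(
                    f"{m.contig}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID={mid}.cds;Parent={mid}\n"
                )


def extract_flanks(
    genome: ReferenceGenome,
    gene: GeneModel,
    up_len: int,
    down_len: int,
) -> tuple[str, str]:
    """Homology arms around the junction, 5'->3' in gene orientation.

    The upstream arm is ``up_len`` bases ending at the junction
    (inclusive of the stop codon); the downstream arm is ``down_len``
    bases starting at the junction.  Arms containing N are rejected
    because they cannot be ordered as primers.
    """
    if up_len < 1 or down_len < 1:
        raise ValueError("arm lengths must be >= 1")
    seq = genome.sequences[gene.contig]
    clen = len(seq)
    j = gene.junction
    if gene.strand == "+":
        if j - up_len < 0:
            raise FlankError(
                f"{gene.gene_id}: upstream arm of {up_len} bp exceeds contig start"
            )
        if j + down_len > clen:
            raise FlankError(
                f"{gene.gene_id}: downstream arm of {down_len} bp exceeds contig end"
            )
        up, down = seq[j - up_len : j], seq[j : j + down_len]
    else:
        if j + up_len > clen:
            raise FlankError(
                f"{gene.gene_id}: upstream arm of {up_len} bp exceeds contig end"
            )
        if j - down_len < 0:
            raise FlankError(
                f"{gene.gene_id}: downstream arm of {down_len} bp exceeds contig start"
            )
        up = revcomp(seq[j : j + up_len])
        down = revcomp(seq[j - down_len : j])
    for side, arm in (("upstream", up), ("downstream", down)):
        if "N" in arm:
            raise AmbiguousSequenceError(
                f"{gene.gene_id}: {side} arm contains N bases"
            )
    return up, down


def write_junction_bed(models: list[GeneModel], path: str | Path) -> None:
    """BED6 of 1-bp features at each gene's junction (0-based half-open)."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                f"{m.contig}\t{m.junction}\t{m.junction + 1}\t"
                f"{m.gene_id}_junction\t0\t{m.strand}\n"
            )
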