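"""SpCas9 guide scanning near stop codons.

The design constraint is that the blunt double-strand break must fall
within a few bp of the driver's stop codon, so that the homology-arm
insertion at the junction destroys the protospacer and the integrated
allele cannot be re-cut.  Guides are 20-nt spacers adjacent to an NGG
PAM; the cut is 3 bp 5' of the PAM (between spacer positions 17/18).

Coordinate conventions (plus-strand site): spacer occupies
``[p-20, p)``, PAM ``[p, p+3)``, cut at between-base coordinate
``p - 3``.  A minus-strand site appears on the plus strand as CCN at
``[q, q+3)`` with the spacer at ``[q+3, q+23)`` and cut at ``q + 6``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

from .genome_io import GeneModel, ReferenceGenome, gc_fraction, revcomp

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 30
DEFAULT_MAX_DIST = 5
SPACER_LEN = 20


@dataclass(frozen=True)
class GuideHit:
    """One candidate protospacer near a gene's stop codon."""

    gene_id: str
    spacer: str
    pam: str
    strand: str
    cut: int
    dist_to_stop: int
    gc_frac: float
    genome_match_count: int | None = None

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LEN:
            raise ValueError("spacer must be 20 nt")
        if self.pam[1:3] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.dist_to_stop < 0:
            raise ValueError("dist_to_stop must be >= 0")


def scan_protospacers(
    genome: ReferenceGenome,
    gene: GeneModel,
    window: int = DEFAULT_WINDOW,
) -> list[GuideHit]:
    """All NGG sites on either strand whose spacer lies fully within
    ``[junction - window, junction + window)``.

    Hits are ordered by ascending distance of the cut to the junction,
    plus strand first on ties, then ascending cut coordinate.  A window
    running past the contig is truncated with a warning.
    """
    seq = genome.sequences[gene.contig]
    clen = len(seq)
    j = gene.junction
    lo, hi = j - window, j + window
    if lo < 0 or hi > clen:
        warnings.warn(
            f"{gene.gene_id}: scan window truncated to contig bounds",
            stacklevel=2,
        )
        lo, hi = max(0, lo), min(clen, hi)
    hits: list[GuideHit] = []
    # plus-strand sites: PAM starts at p, spacer [p-20, p) inside window
    for p in range(lo + SPACER_LEN, hi + 1):
        if p + 3 > clen:
            break
        if seq[p + 1 : p + 3] == "GG":
            spacer = seq[p - SPACER_LEN : p]
            cut = p - 3
            hits.append(
                GuideHit(
                    gene_id=gene.gene_id,
                    spacer=spacer,
                    pam=seq[p : p + 3],
                    strand="+",
                    cut=cut,
                    dist_to_stop=abs(cut - j),
                    gc_frac=gc_fraction(spacer),
                )
            )
    # minus-strand sites: plus-strand CCN at [q, q+3), spacer [q+3, q+23)
    for q in range(max(0, lo - 3), hi - SPACER_LEN):
        if q + 3 + SPACER_LEN > clen:
            break
        if q + 3 < lo or q + 3 + SPACER_LEN > hi:
            continue
        if seq[q : q + 2] == "CC":
            spacer = revcomp(seq[q + 3 : q + 3 + SPACER_LEN])
            cut = q + 6
            hits.append(
                GuideHit(
                    gene_id=gene.gene_id,
                    spacer=spacer,
                    pam=revcomp(seq[q : q + 3]),
                    strand="-",
                    cut=cut,
                    dist_to_stop=abs(cut - j),
                    gc_frac=gc_fraction(spacer),
                )
            )
    hits.sort(key=lambda h: (h.dist_to_stop, 0 if h.strand == "+" else 1, h.cut))
    return hits


def _count_sites(seq: str, spacer: str) -> int:
    """Exact spacer+NGG occurrences on one strand of one sequence."""
    n = 0
    start = 0
    while True:
        i = seq.find(spacer, start)
        if i == -1:
            return n
        if i + SPACER_LEN + 3 <= len(seq) and seq[i + SPACER_LEN + 1 : i + SPACER_LEN + 3] == "GG":
            n += 1
        start = i + 1


def count_genome_matches(genome: ReferenceGenome, hit: GuideHit) -> int:
    """Exact occurrences of spacer+NGG on either strand, genome-wide.

    The on-target site counts, so a unique guide returns 1.  This is a
    perfect-match specificity screen; mismatch-tolerant off-target
    scoring is deliberately out of scope.
    """
    total = 0
    for seq in genome.sequences.values():
        total += _count_sites(seq, hit.spacer)
        total += _count_sites(revcomp(seq), hit.spacer)
    return total


def annotate_matches(genome: ReferenceGenome, hits: list[GuideHit]) -> list[GuideHit]:
    """Populate ``genome_match_count`` on each hit."""
    return [
        replace(h, genome_match_count=count_genome_matches(genome, h))
        for h in hits
    ]


def filter_guides(
    hits: list[GuideHit],
    max_dist: int = DEFAULT_MAX_DIST,
    gc_min: float = 0.2,
    gc_max: float = 0.8,
    forbid_tttt: bool = True,
    require_unique: bool = True,
) -> list[GuideHit]:
    """Apply the cut-distance bound and standard gRNA hygiene filters.

    Keeps hits with cut-to-junction distance <= ``max_dist``, GC
    fraction within bounds, no TTTT run (a Pol III terminator), and a
    unique genome match when ``require_unique``.  Scan order is
    preserved.  An empty result means the gene is unusable as a driver.
    """
    out = []
    for h in hits:
        if h.dist_to_stop > max_dist:
            continue
        if not gc_min <= h.gc_frac <= gc_max:
            continue
        if forbid_tttt and "TTTT" in h.spacer:
            continue
        if require_unique:
            if h.genome_match_count is None:
                raise ValueError(
                    f"{h.gene_id}: genome_match_count not populated; "
                    "run annotate_matches first or set require_unique=False"
                )
            if h.genome_match_count != 1:
                continue
        out.append(h)
    return out


def write_guides_tsv(hits: list[GuideHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tspacer\tpam\tstrand\tcut\tdist\tgc\tmatches\n")
        for h in hits:
            fh.write(
                f"{h.gene_id}\t{h.spacer}\t{h.pam}\t{h.strand}\t{h.cut}\t"
                f"{h.dist_to_stop}\t{h.gc_frac:.2f}\t"
                f"{'' if h.genome_match_count is None else h.genome_match_count}\n"
            )


def write_cuts_bed(hits: list[GuideHit], contig_of: dict[str, str], path) -> None:
    """BED6 of 1-bp cut-site features; ``contig_of`` maps gene_id -> contig."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{contig_of[h.gene_id]}\t{h.cut}\t{h.cut + 1}\t"
                f"{h.gene_id}_cut\t0\t{h.strand}\n"
            )
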