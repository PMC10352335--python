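"""In-silico HDR integration, re-cut screening and diagnostic PCR.

HDR is modeled as exact, scarless arm-mediated replacement: the donor
replaces the genomic span between its two arm-match regions.  For a
pure insertion (``delete_downstream == 0``, pathway mode) removing the
inserted interval from the edited contig restores the original genome
exactly.  Transcription is abstracted: the bicistronic mRNA is modeled
by its coding content only (driver ORF, IGG linker, GOI ORF), and both
ORFs are translated with the standard nuclear genetic code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .donor_design import DonorCassette
from .errors import AmbiguousProductError, DesignError, NoAmpliconError
from .genome_io import GeneModel, ReferenceGenome, revcomp, translate
from .guide_design import SPACER_LEN, GuideHit, _count_sites

log = logging.getLogger(__name__)

DEFAULT_RECUT_FLANK = 60
DEFAULT_MIN_ANNEAL = 18


@dataclass(frozen=True)
class EditedLocus:
    """Post-HDR contig with the predicted bicistron and its proteins.

    ``edited_sequence`` is the full modified contig on the plus strand;
    ``insert_interval`` is the 0-based half-open span of non-genomic
    material within it.  ``proteins`` is the ordered pair (driver
    protein, GOI protein), stop codons stripped.
    """

    gene_id: str
    contig: str
    edited_sequence: str
    insert_interval: tuple[int, int]
    bicistron_cds: str
    proteins: tuple[str, str]


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    length: int
    fwd_site: int
    rev_site: int


def integrate(
    genome: ReferenceGenome,
    gene: GeneModel,
    cassette: DonorCassette,
    delete_downstream: int | None = None,
) -> EditedLocus:
    """Splice the donor into the genome at the driver junction.

    Both homology arms are verified base-by-base against the genome
    before splicing; a mismatch is a hard error naming the first
    mismatching offset (this guards against stale annotations).
    ``delete_downstream`` defaults to the value the cassette was built
    with and must agree with it.
    """
    if cassette.gene_id != gene.gene_id:
        raise DesignError(
            f"cassette is for {cassette.gene_id!r}, gene is {gene.gene_id!r}"
        )
    dd = cassette.delete_downstream if delete_downstream is None else delete_downstream
    if dd != cassette.delete_downstream:
        raise DesignError(
            f"delete_downstream={dd} disagrees with cassette "
            f"({cassette.delete_downstream})"
        )
    seq = genome.sequences[gene.contig]
    clen = len(seq)
    # work in gene orientation so the splice arithmetic is strand-free
    if gene.strand == "+":
        oriented, j = seq, gene.junction
    else:
        oriented, j = revcomp(seq), clen - gene.junction

    up = cassette.part("UpTA")
    down = cassette.part("DownTA")
    # UpTA ends 3 bp before the junction in library mode (stop re-added
    # as its own part), at the junction in pathway mode
    up_end = j - 3 if cassette.mode == "library" else j
    up_start = up_end - len(up)
    down_start = j + dd
    down_end = down_start + len(down)
    if up_start < 0 or down_end > clen:
        raise DesignError(f"{gene.gene_id}: arms extend outside the contig")
    for side, arm, ref in (
        ("upstream", up, oriented[up_start:up_end]),
        ("downstream", down, oriented[down_start:down_end]),
    ):
        if arm != ref:
            off = next(i for i, (a, b) in enumerate(zip(arm, ref)) if a != b)
            raise DesignError(
                f"{gene.gene_id}: {side} arm mismatches genome at offset {off} "
                f"(arm {arm[off]!r} vs genome {ref[off]!r})"
            )
    full = cassette.full_sequence
    edited_oriented = oriented[:up_start] + full + oriented[down_end:]
    ins_start = up_start + len(up)
    ins_end = up_start + len(full) - len(down)
    if gene.strand == "+":
        edited = edited_oriented
        insert_interval = (ins_start, ins_end)
    else:
        edited = revcomp(edited_oriented)
        elen = len(edited_oriented)
        insert_interval = (elen - ins_end, elen - ins_start)

    # bicistron coding content: driver sense codons (+FLAG in library
    # mode) + driver stop + IGG + GOI(+tag) + goi stop
    driver_cds = gene.spliced_cds(genome)
    sense, driver_stop = driver_cds[:-3], driver_cds[-3:]
    goi = cassette.part("GOI")
    tag = cassette.part("tag") if cassette.has_part("tag") else ""
    goi_stop = cassette.part("goi_stop")
    igg = cassette.part("IGG")
    if cassette.mode == "library":
        flag = cassette.part("FLAG")
        driver_orf = sense + flag
        driver_stop = cassette.part("driver_stop")
    else:
        driver_orf = sense
    bicistron = driver_orf + driver_stop + igg + goi + tag + goi_stop
    driver_protein = translate(driver_orf)
    goi_protein = translate(goi + tag)
    if "*" in driver_protein or "*" in goi_protein:
        raise DesignError(f"{gene.gene_id}: premature stop in bicistron ORF")
    return EditedLocus(
        gene_id=gene.gene_id,
        contig=gene.contig,
        edited_sequence=edited,
        insert_interval=insert_interval,
        bicistron_cds=bicistron,
        proteins=(driver_protein, goi_protein),
    )


def recut_check(
    edited: EditedLocus, guide: GuideHit, flank: int = DEFAULT_RECUT_FLANK
) -> str:
    """'disrupted' if the guide's spacer+NGG no longer occurs near the
    insert on either strand of the edited sequence, else 'intact'.

    An intact site means Cas9 could re-cut the integrated allele; the
    caller should treat it as a design warning.
    """
    a, b = edited.insert_interval
    lo = max(0, a - flank - SPACER_LEN - 3)
    hi = min(len(edited.edited_sequence), b + flank + SPACER_LEN + 3)
    region = edited.edited_sequence[lo:hi]
    n = _count_sites(region, guide.spacer) + _count_sites(
        revcomp(region), guide.spacer
    )
    return "intact" if n else "disrupted"


def in_silico_pcr(
    template: str,
    fwd: str,
    rev: str,
    min_anneal: int = DEFAULT_MIN_ANNEAL,
) -> Amplicon:
    """Predict the single product of a primer pair on a linear template.

    A primer anneals where its 3'-terminal ``min_anneal`` nt match the
    template exactly; 5' tails are allowed and appear in the product.
    The amplicon spans the forward primer's 5' tail through the reverse
    primer's 5' tail.  No site for either primer, or more than one
    possible product, is an error.
    """
    template = template.upper()
    if len(fwd) < min_anneal or len(rev) < min_anneal:
        raise DesignError(f"primers must be at least {min_anneal} nt")
    k = min_anneal
    fseed = fwd[-k:].upper()
    rseed = revcomp(rev[-k:].upper())  # plus-strand image of rev anneal site

    def _sites(seed: str) -> list[int]:
        out, start = [], 0
        while True:
            i = template.find(seed, start)
            if i == -1:
                return out
            out.append(i)
            start = i + 1

    fsites = _sites(fseed)
    rsites = _sites(rseed)
    if not fsites or not rsites:
        missing = []
        if not fsites:
            missing.append("forward")
        if not rsites:
            missing.append("reverse")
        raise NoAmpliconError(
            f"no annealing site for {' and '.join(missing)} primer(s)"
        )
    pairs = [(i, j) for i in fsites for j in rsites if j >= i]
    if not pairs:
        raise NoAmpliconError(
            "primer sites are in the wrong orientation (reverse site "
            "upstream of forward site)"
        )
    if len(pairs) > 1:
        raise AmbiguousProductError(
            f"multiple possible products from forward sites {fsites} "
            f"and reverse sites {rsites}"
        )
    i, j = pairs[0]
    product = fwd[: len(fwd) - k] + template[i : j + k] + revcomp(rev)[k:]
    return Amplicon(sequence=product, length=len(product), fwd_site=i, rev_site=j)


def edited_locus_to_seqrecord(
    edited: EditedLocus, window: int = 200
) -> SeqRecord:
    """GenBank-ready record of the edited locus around the insert."""
    a, b = edited.insert_interval
    lo = max(0, a - window)
    hi = min(len(edited.edited_sequence), b + window)
    rec = SeqRecord(
        Seq(edited.edited_sequence[lo:hi]),
        id=f"{edited.gene_id}_edit"[:16],
        name=f"{edited.gene_id}_edit"[:16],
        description=(
            f"edited locus for driver {edited.gene_id}; insert at "
            f"[{a},{b}) of contig {edited.contig} (slice offset {lo})"
        ),
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    rec.features.append(
        SeqFeature(
            FeatureLocation(a - lo, b - lo),
            type="misc_feature",
            qualifiers={"label": ["insert"]},
        )
    )
    return rec
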