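"""Donor cassette assembly and one-step PCR primer derivation.

A donor is built from ordered parts around the driver's junction:

* pathway mode:  UpTA(ends with the driver stop) . IGG . GOI . [tag] .
  goi_stop . DownTA
* library mode:  UpTA(ends at the last sense codon) . FLAG .
  driver_stop . IGG . GOI . [tag] . goi_stop . DownTA

Every non-genomic part (IGG linker, FLAG, localization tag, stop) is
short enough to ride on the two PCR primers, so the whole donor is
produced in a single amplification of the bare GOI template.  The
forward primer carries the upstream arm and the IGG linker; the
reverse primer carries the tag, stop and downstream arm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import DesignError
from .genome_io import (
    STOP_CODONS,
    GeneModel,
    ReferenceGenome,
    extract_flanks,
    gc_fraction,
    revcomp,
)

log = logging.getLogger(__name__)

#: Placeholder for the 9-bp IGG6 translation-reinitiation linker.  The
#: real sequence is distributed in supplementary material of its source
#: study; drop it into :class:`LinkerConfig` (or a config file) for
#: production designs.  All logic is sequence-agnostic.
IGG6_PLACEHOLDER = "TACGCTAGC"

#: FLAG epitope (DYKDDDDK) coding sequence, 24 nt, in frame, stop-free.
FLAG_TAG = "GATTACAAGGATGACGACGATAAG"

#: Synthetic stand-in for an MDH3-style C-terminal peroxisomal
#: targeting signal (PTS1 tripeptide SKL), 9 nt.
MDH3_TAG = "TCTAAATTG"

ARM_DEFAULTS = {"library": 40, "pathway": 60}

DEFAULT_ANNEAL_LEN = 20


def _check_tag(name: str, tag: str) -> None:
    if len(tag) % 3:
        raise DesignError(f"{name} tag length {len(tag)} not divisible by 3")
    for i in range(0, len(tag), 3):
        if tag[i : i + 3] in STOP_CODONS:
            raise DesignError(f"{name} tag contains stop codon at nt {i}")


@dataclass(frozen=True)
class LinkerConfig:
    """Sequences shared by every donor in a design run."""

    igg: str = IGG6_PLACEHOLDER
    flag_tag: str = FLAG_TAG
    localization_tag: str | None = None
    goi_stop: str = "TAA"

    def __post_init__(self) -> None:
        if len(self.igg) < 1:
            raise DesignError("IGG linker must be at least 1 bp")
        if self.goi_stop not in STOP_CODONS:
            raise DesignError(f"goi_stop {self.goi_stop!r} is not a stop codon")
        _check_tag("FLAG", self.flag_tag)
        if self.localization_tag:
            _check_tag("localization", self.localization_tag)


@dataclass(frozen=True)
class DonorCassette:
    """Ordered donor parts; ``full_sequence`` is their concatenation."""

    gene_id: str
    mode: str
    parts: tuple[tuple[str, str], ...]
    arm_up_len: int
    arm_down_len: int
    delete_downstream: int = 0

    @property
    def full_sequence(self) -> str:
        return "".join(seq for _, seq in self.parts)

    def part(self, name: str) -> str:
        for n, seq in self.parts:
            if n == name:
                return seq
        raise KeyError(name)

    def has_part(self, name: str) -> bool:
        return any(n == name for n, _ in self.parts)


@dataclass(frozen=True)
class PrimerPair:
    fwd: str
    rev: str
    fwd_anneal_len: int
    rev_anneal_len: int


@dataclass(frozen=True)
class Check:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[Check] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def failures(self) -> list[Check]:
        return [c for c in self.checks if not c.passed]


def _validate_goi(goi_cds: str) -> str:
    """Check the GOI ORF and return it with any terminal stop stripped."""
    goi_cds = goi_cds.upper()
    if len(goi_cds) % 3:
        raise DesignError(f"GOI length {len(goi_cds)} not divisible by 3")
    if not goi_cds.startswith("ATG"):
        raise DesignError("GOI does not start with ATG")
    if goi_cds[-3:] in STOP_CODONS:
        goi_cds = goi_cds[:-3]
    for i in range(0, len(goi_cds), 3):
        if goi_cds[i : i + 3] in STOP_CODONS:
            raise DesignError(f"GOI has internal stop codon at codon {i // 3}")
    return goi_cds


def build_cassette(
    gene: GeneModel,
    genome: ReferenceGenome,
    goi_cds: str,
    cfg: LinkerConfig | None = None,
    mode: str = "pathway",
    arm_up: int | None = None,
    arm_down: int | None = None,
    delete_downstream: int = 0,
) -> DonorCassette:
    """Assemble the ordered donor parts for one driver/GOI pair.

    Arm lengths default to 40 bp (library mode, one-by-one screening of
    candidate drivers) or 60 bp (pathway mode, multiplexed integration).
    ``delete_downstream`` removes that many bp of 3' UTR immediately
    after the junction, reproducing designs that replace the start of
    the terminator region rather than purely inserting.
    """
    cfg = cfg or LinkerConfig()
    if mode not in ARM_DEFAULTS:
        raise DesignError(f"mode must be 'library' or 'pathway', got {mode!r}")
    if delete_downstream < 0:
        raise DesignError("delete_downstream must be >= 0")
    arm_up = ARM_DEFAULTS[mode] if arm_up is None else arm_up
    arm_down = ARM_DEFAULTS[mode] if arm_down is None else arm_down
    goi = _validate_goi(goi_cds)

    parts: list[tuple[str, str]] = []
    if mode == "library":
        # arm ends at the last sense codon; native stop re-added after FLAG
        up_plus_stop, down = extract_flanks(genome, gene, arm_up + 3, arm_down)
        up, driver_stop = up_plus_stop[:-3], up_plus_stop[-3:]
        if driver_stop not in STOP_CODONS:
            raise DesignError(
                f"{gene.gene_id}: sequence before junction is "
                f"{driver_stop!r}, not a stop codon"
            )
        parts.append(("UpTA", up))
        parts.append(("FLAG", cfg.flag_tag))
        parts.append(("driver_stop", driver_stop))
    else:
        up, down = extract_flanks(genome, gene, arm_up, arm_down)
        if up[-3:] not in STOP_CODONS:
            raise DesignError(
                f"{gene.gene_id}: upstream arm does not end with a stop codon"
            )
        parts.append(("UpTA", up))
    if delete_downstream:
        _, down = extract_flanks(
            genome, gene, arm_up, arm_down + delete_downstream
        )
        down = down[delete_downstream:]
    parts.append(("IGG", cfg.igg))
    parts.append(("GOI", goi))
    if cfg.localization_tag:
        parts.append(("tag", cfg.localization_tag))
    parts.append(("goi_stop", cfg.goi_stop))
    parts.append(("DownTA", down))
    return DonorCassette(
        gene_id=gene.gene_id,
        mode=mode,
        parts=tuple(parts),
        arm_up_len=arm_up,
        arm_down_len=arm_down,
        delete_downstream=delete_downstream,
    )


def derive_primers(
    cassette: DonorCassette, anneal_len: int = DEFAULT_ANNEAL_LEN
) -> PrimerPair:
    """The two primers that amplify the full donor from the bare GOI.

    fwd = (UpTA [+ FLAG + driver_stop]) + IGG + first ``anneal_len`` nt
    of the GOI; rev = reverse complement of (last ``anneal_len`` nt of
    GOI + tag + goi_stop + DownTA).  Warnings flag primers over 100 nt
    or annealing regions with GC outside 0.3-0.7.
    """
    goi = cassette.part("GOI")
    if anneal_len > len(goi):
        raise DesignError(
            f"anneal_len {anneal_len} exceeds GOI length {len(goi)}"
        )
    names = [n for n, _ in cassette.parts]
    i_goi = names.index("GOI")
    head = "".join(seq for _, seq in cassette.parts[:i_goi])
    tail = "".join(seq for _, seq in cassette.parts[i_goi + 1 :])
    fwd = head + goi[:anneal_len]
    rev = revcomp(goi[-anneal_len:] + tail)
    for name, primer in (("forward", fwd), ("reverse", rev)):
        if len(primer) > 100:
            warnings.warn(
                f"{cassette.gene_id}: {name} primer is {len(primer)} nt; "
                "synthesis may be impractical",
                stacklevel=2,
            )
    for name, region in (("forward", goi[:anneal_len]), ("reverse", goi[-anneal_len:])):
        gc = gc_fraction(region)
        if not 0.3 <= gc <= 0.7:
            warnings.warn(
                f"{cassette.gene_id}: {name} annealing region GC {gc:.2f} "
                "outside 0.3-0.7",
                stacklevel=2,
            )
    return PrimerPair(
        fwd=fwd, rev=rev, fwd_anneal_len=anneal_len, rev_anneal_len=anneal_len
    )


_GRAMMARS = {
    "pathway": ("UpTA", "IGG", "GOI", "tag?", "goi_stop", "DownTA"),
    "library": (
        "UpTA",
        "FLAG",
        "driver_stop",
        "IGG",
        "GOI",
        "tag?",
        "goi_stop",
        "DownTA",
    ),
}


def _order_matches(names: list[str], grammar: tuple[str, ...]) -> bool:
    i = 0
    for token in grammar:
        optional = token.endswith("?")
        want = token.rstrip("?")
        if i < len(names) and names[i] == want:
            i += 1
        elif not optional:
            return False
    return i == len(names)


def validate_cassette(
    cassette: DonorCassette, cfg: LinkerConfig | None = None
) -> ValidationReport:
    """Structural checks on an assembled donor; failures do not raise."""
    cfg = cfg or LinkerConfig()
    report = ValidationReport()
    full = cassette.full_sequence
    n_igg = full.count(cfg.igg)
    report.checks.append(
        Check("igg_single_copy", n_igg == 1, f"IGG occurs {n_igg} times")
    )
    # a stop codon must immediately precede IGG, in frame with the CDS
    names = [n for n, _ in cassette.parts]
    try:
        i_igg = names.index("IGG")
        before = "".join(s for _, s in cassette.parts[:i_igg])
        stop_ok = len(before) >= 3 and before[-3:] in STOP_CODONS
        report.checks.append(
            Check(
                "stop_before_igg",
                stop_ok,
                f"3 nt before IGG are {before[-3:]!r}" if len(before) >= 3 else "no sequence before IGG",
            )
        )
    except ValueError:
        report.checks.append(Check("stop_before_igg", False, "no IGG part"))
    goi = cassette.part("GOI") if cassette.has_part("GOI") else ""
    goi_ok, detail = True, "ORF intact"
    if not goi.startswith("ATG"):
        goi_ok, detail = False, "GOI does not start with ATG"
    elif len(goi) % 3:
        goi_ok, detail = False, f"GOI length {len(goi)} not divisible by 3"
    else:
        for i in range(0, len(goi), 3):
            if goi[i : i + 3] in STOP_CODONS:
                goi_ok, detail = False, f"internal stop at codon {i // 3}"
                break
    report.checks.append(Check("goi_orf_intact", goi_ok, detail))
    arms_ok = all(
        "N" not in cassette.part(p)
        for p in ("UpTA", "DownTA")
        if cassette.has_part(p)
    )
    report.checks.append(Check("arms_n_free", arms_ok))
    report.checks.append(
        Check(
            "part_order",
            _order_matches(names, _GRAMMARS.get(cassette.mode, ())),
            f"parts: {' '.join(names)}",
        )
    )
    return report


def cassette_to_seqrecord(cassette: DonorCassette) -> SeqRecord:
    """Annotated GenBank-ready record with one feature per part."""
    record = SeqRecord(
        Seq(cassette.full_sequence),
        id=f"{cassette.gene_id}_donor"[:16],
        name=f"{cassette.gene_id}_donor"[:16],
        description=f"donor cassette for driver {cassette.gene_id} ({cassette.mode} mode)",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    pos = 0
    for name, seq in cassette.parts:
        record.features.append(
            SeqFeature(
                FeatureLocation(pos, pos + len(seq)),
                type="misc_feature",
                qualifiers={"label": [name]},
            )
        )
        pos += len(seq)
    return record


def write_oligo_sheet(rows: list[tuple[str, str]], path) -> None:
    """TSV order sheet: primer name, sequence, length, GC%."""
    with open(path, "w") as fh:
        fh.write("name\tsequence\tlength\tgc_percent\n")
        for name, seq in rows:
            fh.write(f"{name}\t{seq}\t{len(seq)}\t{100 * gc_fraction(seq):.1f}\n")
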