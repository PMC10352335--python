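"""End-to-end design runs and the consolidated design report.

``run_design`` chains the whole workflow: driver selection from the
abundance table, guide scanning and filtering at each driver's stop
codon, donor and primer design, in-silico integration and re-cut
screening, expression prediction, and round planning.  Drivers whose
junction offers no guide passing the filters are reported as
"abandoned" rather than silently dropped.  The report is deterministic
for a given config and serializes losslessly to JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from . import __version__
from .donor_design import (
    FLAG_TAG,
    IGG6_PLACEHOLDER,
    DonorCassette,
    LinkerConfig,
    build_cassette,
    cassette_to_seqrecord,
    derive_primers,
    validate_cassette,
    write_oligo_sheet,
)
from .driver_select import (
    DEFAULT_MIN_ABUNDANCE,
    DriverCandidate,
    assign_tiers,
    filter_drivers,
    load_abundance,
)
from .edit_sim import integrate, recut_check
from .errors import DesignError
from .expression_model import CouplingParams, predict_goi_level
from .genome_io import read_annotation, read_genome
from .guide_design import (
    annotate_matches,
    filter_guides,
    scan_protospacers,
    write_cuts_bed,
)
from .multiplex_plan import EditDesign, check_conflicts, plan_rounds

log = logging.getLogger(__name__)


@dataclass
class DesignConfig:
    """Everything a design run needs; loadable from TOML or JSON."""

    genome: str
    annotation: str
    abundance: str
    gois: str | dict  # FASTA path, or mapping goi_id -> CDS
    goi_driver_map: dict | None = None  # explicit goi -> driver pairing
    min_abundance: float = DEFAULT_MIN_ABUNDANCE
    q_high: float = 0.9
    q_low: float = 0.5
    window: int = 30
    max_dist: int = 5
    gc_min: float = 0.2
    gc_max: float = 0.8
    forbid_tttt: bool = True
    require_unique: bool = True
    mode: str = "pathway"
    arm_up: int | None = None
    arm_down: int | None = None
    delete_downstream: int = 0
    igg: str = IGG6_PLACEHOLDER
    flag_tag: str = FLAG_TAG
    localization_tag: str | None = None
    goi_stop: str = "TAA"
    anneal_len: int = 20
    capacity: int = 4
    eta: float = 0.55
    rho: float = 0.50
    isoform: str = "first"
    seed: int = 1

    @classmethod
    def from_file(cls, path: str | Path) -> "DesignConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path) as fh:
                data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("genome", "annotation", "abundance"):
            d[key] = str(d[key])
        if not isinstance(d["gois"], dict):
            d["gois"] = str(d["gois"])
        return d


@dataclass
class DesignReport:
    """Per-gene design records plus provenance (version, config, seed)."""

    records: list[dict]
    rounds: list[list[str]]
    conflicts: dict
    version: str
    config: dict
    seed: int
    n_excluded_genes: int = 0
    n_abandoned: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DesignReport":
        return cls(**json.loads(text))


def _load_gois(gois) -> list[tuple[str, str]]:
    if isinstance(gois, dict):
        return list(gois.items())
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(gois), "fasta")]


def _guide_dict(hit) -> dict:
    return {
        "spacer": hit.spacer,
        "pam": hit.pam,
        "strand": hit.strand,
        "cut": hit.cut,
        "dist_to_stop": hit.dist_to_stop,
        "gc_frac": round(hit.gc_frac, 4),
        "genome_match_count": hit.genome_match_count,
    }


def run_design(
    config: DesignConfig, out_dir: str | Path | None = None
) -> DesignReport:
    """Execute the full pipeline and return the consolidated report.

    Driver/GOI pairing: an explicit ``goi_driver_map`` wins; otherwise
    GOIs are assigned in input order to the highest-ranked drivers that
    have a passing guide.  The best guide per driver is the one with
    minimal cut-to-junction distance (scan order breaks ties).  With
    ``out_dir`` set, report.json, designs.tsv, oligos.tsv, donors.gb
    and cuts.bed are written there.
    """
    genome = read_genome(config.genome)
    models = read_annotation(config.annotation, genome, isoform=config.isoform)
    records_in = load_abundance(config.abundance)
    candidates = assign_tiers(
        filter_drivers(records_in, models, config.min_abundance),
        config.q_high,
        config.q_low,
    )
    gois = _load_gois(config.gois)
    linker = LinkerConfig(
        igg=config.igg,
        flag_tag=config.flag_tag,
        localization_tag=config.localization_tag,
        goi_stop=config.goi_stop,
    )
    params = CouplingParams(eta=config.eta, rho=config.rho)
    by_id = {c.gene_id: c for c in candidates}
    model_by_id = {m.gene_id: m for m in models}

    def best_guide(candidate: DriverCandidate):
        hits = scan_protospacers(genome, candidate.gene, config.window)
        if config.require_unique:
            hits = annotate_matches(genome, hits)
        passing = filter_guides(
            hits,
            max_dist=config.max_dist,
            gc_min=config.gc_min,
            gc_max=config.gc_max,
            forbid_tttt=config.forbid_tttt,
            require_unique=config.require_unique,
        )
        return passing[0] if passing else None

    records: list[dict] = []
    designed: list[tuple[DriverCandidate, str, str, object]] = []
    if config.goi_driver_map:
        pairing = []
        for goi_id, driver_id in config.goi_driver_map.items():
            if driver_id not in by_id:
                raise DesignError(
                    f"driver {driver_id!r} (for GOI {goi_id!r}) is not a "
                    "candidate above the abundance threshold"
                )
            cds = dict(gois).get(goi_id)
            if cds is None:
                raise DesignError(f"no CDS provided for GOI {goi_id!r}")
            pairing.append((by_id[driver_id], goi_id, cds))
        for cand, goi_id, cds in pairing:
            guide = best_guide(cand)
            if guide is None:
                records.append(_abandoned_record(cand))
            else:
                designed.append((cand, goi_id, cds, guide))
    else:
        queue = list(gois)
        for cand in candidates:
            if not queue:
                break
            guide = best_guide(cand)
            if guide is None:
                records.append(_abandoned_record(cand))
                continue
            goi_id, cds = queue.pop(0)
            designed.append((cand, goi_id, cds, guide))
        if queue:
            raise DesignError(
                f"{len(queue)} GOI(s) left unassigned: not enough drivers "
                "with passing guides"
            )

    cassettes: list[DonorCassette] = []
    plan_inputs: list[EditDesign] = []
    cut_hits = []
    oligo_rows: list[tuple[str, str]] = []
    for cand, goi_id, cds, guide in designed:
        gene = model_by_id[cand.gene_id]
        cassette = build_cassette(
            gene,
            genome,
            cds,
            linker,
            mode=config.mode,
            arm_up=config.arm_up,
            arm_down=config.arm_down,
            delete_downstream=config.delete_downstream,
        )
        validation = validate_cassette(cassette, linker)
        primers = derive_primers(cassette, config.anneal_len)
        edited = integrate(genome, gene, cassette)
        recut = recut_check(edited, guide)
        estimate = predict_goi_level(cand.abundance, params, gene_id=cand.gene_id)
        arm_up = cassette.arm_up_len
        arm_down = cassette.arm_down_len
        plan_inputs.append(
            EditDesign(
                goi_id=goi_id,
                driver_id=cand.gene_id,
                contig=gene.contig,
                junction=gene.junction,
                spacer=guide.spacer,
                arm_up=arm_up,
                arm_down=arm_down,
            )
        )
        cassettes.append(cassette)
        cut_hits.append(guide)
        fwd_name = f"{cand.gene_id}_{goi_id}_F"
        rev_name = f"{cand.gene_id}_{goi_id}_R"
        oligo_rows += [(fwd_name, primers.fwd), (rev_name, primers.rev)]
        records.append(
            {
                "driver": cand.gene_id,
                "tier": cand.tier,
                "rank": cand.rank,
                "abundance": cand.abundance,
                "goi": goi_id,
                "status": "designed",
                "guide": _guide_dict(guide),
                "cassette_id": f"{cand.gene_id}_{goi_id}_donor",
                "primers": {
                    "fwd_name": fwd_name,
                    "fwd": primers.fwd,
                    "rev_name": rev_name,
                    "rev": primers.rev,
                },
                "validation": {
                    "ok": validation.ok,
                    "failures": [c.name for c in validation.failures],
                },
                "recut": recut,
                "expression": {
                    "point": estimate.point,
                    "low": estimate.low,
                    "high": estimate.high,
                    "coupling_percent": estimate.coupling_percent,
                },
                "round": None,  # filled below
            }
        )

    plan = plan_rounds(plan_inputs, config.capacity)
    round_of = {
        gid: i + 1 for i, rnd in enumerate(plan.rounds) for gid in rnd
    }
    for rec in records:
        if rec["status"] == "designed":
            rec["round"] = round_of[rec["driver"]]
    conflicts = check_conflicts(plan_inputs)
    report = DesignReport(
        records=records,
        rounds=[list(r) for r in plan.rounds],
        conflicts={"errors": conflicts.errors, "warnings": conflicts.warnings},
        version=__version__,
        config=config.echo(),
        seed=config.seed,
        n_excluded_genes=len(models.excluded),
        n_abandoned=sum(1 for r in records if r["status"] == "abandoned"),
    )
    if out_dir is not None:
        _write_outputs(
            Path(out_dir), report, cassettes, cut_hits, model_by_id, oligo_rows
        )
    return report


def _abandoned_record(cand: DriverCandidate) -> dict:
    return {
        "driver": cand.gene_id,
        "tier": cand.tier,
        "rank": cand.rank,
        "abundance": cand.abundance,
        "goi": None,
        "status": "abandoned",
        "guide": None,
        "cassette_id": None,
        "primers": None,
        "validation": None,
        "recut": None,
        "expression": None,
        "round": None,
    }


def _write_outputs(out_dir, report, cassettes, cut_hits, model_by_id, oligo_rows):
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(report.to_json())
    with open(out_dir / "designs.tsv", "w") as fh:
        fh.write(
            "driver\ttier\trank\tabundance\tgoi\tstatus\tspacer\tdist\t"
            "recut\tvalidation\texpr_point\tround\n"
        )
        for r in report.records:
            guide = r["guide"] or {}
            expr = r["expression"] or {}
            fh.write(
                f"{r['driver']}\t{r['tier']}\t{r['rank']}\t{r['abundance']:.6g}\t"
                f"{r['goi'] or ''}\t{r['status']}\t{guide.get('spacer', '')}\t"
                f"{guide.get('dist_to_stop', '')}\t{r['recut'] or ''}\t"
                f"{'ok' if r['validation'] and r['validation']['ok'] else ''}\t"
                f"{expr.get('point', '')}\t{r['round'] or ''}\n"
            )
    write_oligo_sheet(oligo_rows, out_dir / "oligos.tsv")
    with open(out_dir / "donors.gb", "w") as fh:
        for cassette in cassettes:
            SeqIO.write(cassette_to_seqrecord(cassette), fh, "genbank")
    contig_of = {gid: m.contig for gid, m in model_by_id.items()}
    write_cuts_bed(cut_hits, contig_of, out_dir / "cuts.bed")
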