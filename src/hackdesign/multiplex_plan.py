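"""Partition designs into multiplexed editing rounds and find conflicts.

Marker-free multiplexed CRISPR integrates several donors per
transformation; a batch of n designs at a per-round guide capacity c
needs ceil(n / c) sequential rounds.  The default capacity of 4 matches
an 8-gene module completed in two rounds.  Conflict checking catches
designs that cannot coexist: two GOIs hitched to the same driver,
identical spacers across designs, and homology arms overlapping another
design's edit window on the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DesignError

DEFAULT_CAPACITY = 4


@dataclass(frozen=True)
class EditDesign:
    """The facts about one planned integration that planning needs."""

    goi_id: str
    driver_id: str
    contig: str
    junction: int
    spacer: str
    arm_up: int = 60
    arm_down: int = 60

    @property
    def window(self) -> tuple[int, int]:
        """Genomic span touched by the homology arms."""
        return (self.junction - self.arm_up, self.junction + self.arm_down)


@dataclass(frozen=True)
class RoundPlan:
    rounds: tuple[tuple[str, ...], ...]
    capacity: int

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


@dataclass
class ConflictReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _driver_id(design) -> str:
    return design if isinstance(design, str) else design.driver_id


def plan_rounds(designs, capacity: int = DEFAULT_CAPACITY) -> RoundPlan:
    """Greedy fill in input (priority) order; deterministic.

    ``designs`` may be :class:`EditDesign` objects or bare driver gene
    ids.  Duplicate driver ids are an error: one driver hosts one GOI.
    """
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    ids = [_driver_id(d) for d in designs]
    seen = set()
    for gid in ids:
        if gid in seen:
            raise DesignError(f"duplicate driver gene {gid!r} in plan input")
        seen.add(gid)
    rounds = tuple(
        tuple(ids[i : i + capacity]) for i in range(0, len(ids), capacity)
    )
    return RoundPlan(rounds=rounds, capacity=capacity)


def check_conflicts(designs: list[EditDesign]) -> ConflictReport:
    """All-pairs cross-design screen; errors and warnings, never raises.

    Errors: duplicate driver usage, identical spacers.  Warnings: one
    design's homology-arm window overlapping another's on the genome
    (simultaneous HDR at overlapping windows risks chimeric repair).
    """
    report = ConflictReport()
    by_driver: dict[str, list[str]] = {}
    by_spacer: dict[str, list[str]] = {}
    for d in designs:
        by_driver.setdefault(d.driver_id, []).append(d.goi_id)
        by_spacer.setdefault(d.spacer, []).append(d.goi_id)
    for driver, gois in by_driver.items():
        if len(gois) > 1:
            report.errors.append(
                f"driver {driver!r} hosts multiple GOIs: {', '.join(gois)}"
            )
    for spacer, gois in by_spacer.items():
        if len(gois) > 1:
            report.errors.append(
                f"identical spacer {spacer!r} in designs: {', '.join(gois)}"
            )
    for i, a in enumerate(designs):
        for b in designs[i + 1 :]:
            if a.contig != b.contig or a.driver_id == b.driver_id:
                continue
            a0, a1 = a.window
            b0, b1 = b.window
            if a0 < b1 and b0 < a1:
                report.warnings.append(
                    f"edit windows of {a.driver_id!r} and {b.driver_id!r} "
                    f"overlap on {a.contig} ([{a0},{a1}) vs [{b0},{b1}))"
                )
    return report
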