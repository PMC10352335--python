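"""Driver-gene selection from a protein-abundance table.

Candidate drivers are endogenous genes whose protein abundance (an
iBAQ-like arbitrary unit) exceeds a threshold, default 5e5, under the
intended cultivation conditions.  Candidates are ranked by abundance
and partitioned into high/medium/low tiers by quantiles so that a gene
of interest can be hitched to a driver of the desired strength.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DuplicateIdError
from .genome_io import GeneModel

log = logging.getLogger(__name__)

DEFAULT_MIN_ABUNDANCE = 5e5

REQUIRED_COLUMNS = ("protein_id", "gene_id", "abundance")


@dataclass(frozen=True)
class AbundanceRecord:
    protein_id: str
    gene_id: str
    abundance: float

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError(
                f"{self.protein_id}: abundance must be nonnegative"
            )


@dataclass(frozen=True)
class DriverCandidate:
    """A gene accepted as a potential driver, ranked by abundance."""

    gene: GeneModel
    abundance: float
    rank: int
    tier: str | None = None

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id


class RecordList(list):
    """Parsed abundance records; ``n_dropped`` counts unusable rows."""

    def __init__(self, records=(), n_dropped: int = 0):
        super().__init__(records)
        self.n_dropped = n_dropped


def load_abundance(path) -> RecordList:
    """Read a TSV with columns protein_id, gene_id, abundance.

    Rows with missing or non-numeric abundance are dropped and counted
    in ``.n_dropped``.  A missing column or duplicate protein_id is a
    hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "gene_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    dupes = df["protein_id"][df["protein_id"].duplicated()]
    if not dupes.empty:
        raise DuplicateIdError(
            f"{path}: duplicate protein_id {dupes.iloc[0]!r}"
        )
    values = pd.to_numeric(df["abundance"], errors="coerce")
    keep = values.notna() & (values >= 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropped %d rows with unusable abundance", n_dropped)
    records = [
        AbundanceRecord(row.protein_id, row.gene_id, float(val))
        for row, val in zip(df[keep].itertuples(index=False), values[keep])
    ]
    return RecordList(records, n_dropped)


def filter_drivers(
    records: list[AbundanceRecord],
    genes: list[GeneModel],
    min_abundance: float = DEFAULT_MIN_ABUNDANCE,
) -> list[DriverCandidate]:
    """Keep records strictly above the abundance threshold with a gene model.

    Output is sorted descending by abundance (ties broken
    lexicographically by gene_id) and ranked 1..n.  An empty result is
    a warning, not an error.
    """
    by_gene = {g.gene_id: g for g in genes}
    kept = [
        r
        for r in records
        if r.abundance > min_abundance and r.gene_id in by_gene
    ]
    kept.sort(key=lambda r: (-r.abundance, r.gene_id))
    if not kept:
        warnings.warn(
            f"no drivers above abundance threshold {min_abundance:g}",
            stacklevel=2,
        )
    return [
        DriverCandidate(gene=by_gene[r.gene_id], abundance=r.abundance, rank=i)
        for i, r in enumerate(kept, start=1)
    ]


def assign_tiers(
    candidates: list[DriverCandidate],
    q_high: float = 0.9,
    q_low: float = 0.5,
) -> list[DriverCandidate]:
    """Partition candidates into high/medium/low abundance tiers.

    Thresholds are the ``q_high`` and ``q_low`` quantiles (linear
    interpolation) of the candidate abundances: abundance >= high
    quantile -> "high", >= low quantile -> "medium", else "low".
    With fewer than two candidates every candidate is "high".
    """
    if not 0 < q_low < q_high < 1:
        raise ValueError("need 0 < q_low < q_high < 1")
    if not candidates:
        return []
    if len(candidates) < 2:
        warnings.warn(
            "fewer than 2 candidates; assigning tier 'high' to all",
            stacklevel=2,
        )
        return [replace(c, tier="high") for c in candidates]
    values = np.array([c.abundance for c in candidates], dtype=float)
    hi = float(np.quantile(values, q_high))
    lo = float(np.quantile(values, q_low))
    out = []
    for c in candidates:
        if c.abundance >= hi:
            tier = "high"
        elif c.abundance >= lo:
            tier = "medium"
        else:
            tier = "low"
        out.append(replace(c, tier=tier))
    return out


def write_candidates(candidates: list[DriverCandidate], path) -> None:
    """TSV out: gene_id, abundance, tier, rank."""
    pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in candidates],
            "abundance": [c.abundance for c in candidates],
            "tier": [c.tier or "" for c in candidates],
            "rank": [c.rank for c in candidates],
        }
    ).to_csv(path, sep="\t", index=False)
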