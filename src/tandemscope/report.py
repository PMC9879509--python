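"""Per-genome summary rows with explicitly defined derived columns.

Derived columns and their printed precision:

* pct_tr             = 100 * tr_total_len_bp / genome_size_bp      (2 dp)
* repeats_per_bp     = total_units / genome_size_bp                (7 dp)
* pct_aatr_proteins  = 100 * n_aatr_proteins / n_proteins          (2 dp)
* pct_tr_in_orf      = 100 * n_tr_in_orf / n_tr                    (integer)
* pct_intergenic_div3= 100 * intergenic_div3 / intergenic          (integer)

pct_tr_in_orf divides by the total TR count, not the intergenic count:
that formula, not the header's literal ratio, reproduces the published
derived values from the published primary counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .aatr_mapper import GENIC, INTERGENIC, TrOrfAssignment, resolve_boundary
from .core_io import GenomeRecord, ProteinRecord
from .repeat_finder import AATR, TRRegion


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    genome_size_bp: int
    n_tr: int
    tr_total_len_bp: int
    total_units: int
    n_proteins: int
    n_tr_in_orf: int
    n_aatr_proteins: int
    n_intergenic: int = 0
    n_intergenic_div3: int = 0

    @property
    def pct_tr(self) -> float:
        return round(100.0 * self.tr_total_len_bp / self.genome_size_bp, 2)

    @property
    def repeats_per_bp(self) -> float:
        return round(self.total_units / self.genome_size_bp, 7)

    @property
    def pct_aatr_proteins(self) -> Optional[float]:
        if self.n_proteins == 0:
            return None
        return round(100.0 * self.n_aatr_proteins / self.n_proteins, 2)

    @property
    def pct_tr_in_orf(self) -> Optional[int]:
        if self.n_tr == 0:
            return None
        return round(100.0 * self.n_tr_in_orf / self.n_tr)

    @property
    def pct_intergenic_div3(self) -> Optional[int]:
        if self.n_intergenic == 0:
            return None
        return round(100.0 * self.n_intergenic_div3 / self.n_intergenic)


def summarize_genome(genome: GenomeRecord, regions: Sequence[TRRegion],
                     assignments: Sequence[TrOrfAssignment],
                     proteome: Sequence[ProteinRecord],
                     aatrs: Sequence[AATR],
                     boundary_genic_if_majority: bool = True) -> GenomeSummary:
    """Tally the primary counts of one genome into a summary row.

    Boundary-context regions are folded into the two-way genic/intergenic
    split before counting (default: genic when >=50% of the region lies
    inside the ORF).
    """
    resolved = resolve_boundary(assignments, boundary_genic_if_majority)
    intergenic = [a for a in resolved if a.context == INTERGENIC]
    return GenomeSummary(
        genome_id=genome.id,
        genome_size_bp=len(genome),
        n_tr=len(regions),
        tr_total_len_bp=sum(r.region_len for r in regions),
        total_units=sum(r.copies for r in regions),
        n_proteins=len(proteome),
        n_tr_in_orf=sum(1 for a in resolved if a.context == GENIC),
        n_aatr_proteins=len({a.protein_id for a in aatrs}),
        n_intergenic=len(intergenic),
        n_intergenic_div3=sum(1 for a in intergenic if a.unit_div3),
    )


#: column order of the summary TSV
SUMMARY_COLUMNS = (
    "genome_id", "genome_size_bp", "n_tr", "tr_total_len_bp", "pct_tr",
    "total_units", "repeats_per_bp", "n_proteins", "n_tr_in_orf",
    "n_aatr_proteins", "pct_aatr_proteins", "pct_tr_in_orf",
    "pct_intergenic_div3",
)


def _row_values(row: GenomeSummary) -> list:
    return [getattr(row, c) for c in SUMMARY_COLUMNS]


def aggregate_summaries(rows: Sequence[GenomeSummary]) -> tuple[dict, dict]:
    """(average row, sum row) over the numeric summary columns.

    The average row is the column-wise arithmetic mean of the per-genome
    values (including the derived percentage columns, matching the
    published table's average-row semantics); the sum row covers the
    primary count columns only.
    """
    if not rows:
        raise ValueError("need at least one summary row")
    numeric = [c for c in SUMMARY_COLUMNS if c != "genome_id"]
    count_cols = ("genome_size_bp", "n_tr", "tr_total_len_bp", "total_units",
                  "n_proteins", "n_tr_in_orf", "n_aatr_proteins")
    average: dict = {"genome_id": "average"}
    total: dict = {"genome_id": "sum"}
    for col in numeric:
        values = [getattr(r, col) for r in rows]
        present = [v for v in values if v is not None and not (
            isinstance(v, float) and math.isnan(v))]
        average[col] = sum(present) / len(present) if present else None
        if col in count_cols:
            total[col] = sum(present)
    return average, total


def write_summary_tsv(rows: Sequence[GenomeSummary], path: str | Path,
                      with_aggregates: bool = True) -> None:
    def fmt(v) -> str:
        if v is None:
            return "NA"
        if isinstance(v, float):
            return f"{v:g}"
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(fmt(v) for v in _row_values(row)) + "\n")
        if with_aggregates and rows:
            average, total = aggregate_summaries(rows)
            for agg in (average, total):
                fh.write("\t".join(fmt(agg.get(c)) for c in SUMMARY_COLUMNS) + "\n")
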