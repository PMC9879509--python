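"""Unit-number heterogeneity of TR regions within a read population.

Because the repeats are perfect, exact anchor matching is sufficient: a
read spans a region iff it contains the unique flanking anchors in order,
and the unit count between the anchors is read off by exact unit
matching.  Spanning variants must differ by whole units; partial-unit
spans count as non-spanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core_io import GenomeRecord, reverse_complement
from .repeat_finder import TRRegion, flanking_partials


@dataclass
class ReadSupport:
    region_id: str
    spanning_counts: dict[int, int] = field(default_factory=dict)
    non_spanning: int = 0
    assessable: bool = True


def _region_id(region: TRRegion) -> str:
    return f"{region.contig_id}:{region.start}-{region.end}"


def count_spanning_units(reads: Sequence[str], region: TRRegion,
                         genome: GenomeRecord,
                         anchor_len: int = 15) -> ReadSupport:
    """Tally spanning reads by the whole-unit count they carry.

    Anchors are the ``anchor_len`` bases flanking the extended periodic
    interval (region plus partial flanks).  Both read orientations are
    tried.  A region whose anchors are not unique in the genome is
    flagged un-assessable.
    """
    seq = genome.sequence
    a, b = flanking_partials(region, genome)
    ext_start, ext_end = region.start - a, region.end + b
    if ext_start < anchor_len or ext_end + anchor_len > len(seq):
        return ReadSupport(region_id=_region_id(region), assessable=False)
    left = seq[ext_start - anchor_len : ext_start]
    right = seq[ext_end : ext_end + anchor_len]
    if seq.count(left) != 1 or seq.count(right) != 1:
        return ReadSupport(region_id=_region_id(region), assessable=False)
    unit = seq[ext_start : ext_start + region.unit_len]  # rotation at ext start
    m = region.unit_len
    partial_tail = (ext_end - ext_start) % m
    tail = unit[:partial_tail]
    support = ReadSupport(region_id=_region_id(region))
    for read in reads:
        counted = False
        for oriented in (read, reverse_complement(read)):
            li = oriented.find(left)
            if li == -1:
                continue
            ri = oriented.find(right, li + anchor_len)
            if ri == -1:
                support.non_spanning += 1  # one anchor only
            else:
                between = oriented[li + anchor_len : ri]
                k = _whole_unit_count(between, unit, tail)
                if k is not None:
                    support.spanning_counts[k] = \
                        support.spanning_counts.get(k, 0) + 1
                else:
                    support.non_spanning += 1  # partial-unit span
            counted = True
            break
        if not counted and any(
                right in o or unit in o
                for o in (read, reverse_complement(read))):
            support.non_spanning += 1
    return support


def _whole_unit_count(between: str, unit: str, tail: str) -> Optional[int]:
    """Number of whole units k with between == unit * k + tail, else None."""
    m = len(unit)
    if (len(between) - len(tail)) % m != 0 or len(between) < len(tail):
        return None
    k = (len(between) - len(tail)) // m
    if between == unit * k + tail:
        return k
    return None


@dataclass(frozen=True)
class VariationCensus:
    n_assessable: int
    n_variable: int
    variable_region_ids: tuple[str, ...]

    @property
    def fraction_variable(self) -> float:
        if self.n_assessable == 0:
            return float("nan")
        return self.n_variable / self.n_assessable


def variable_region_census(supports: Sequence[ReadSupport],
                           min_reads: int = 2) -> VariationCensus:
    """Count regions with >= 2 distinct spanning unit-counts, each backed
    by >= min_reads reads.  Regions with no spanning reads are excluded
    from the denominator."""
    assessable = [s for s in supports if s.assessable and s.spanning_counts]
    variable = [
        s for s in assessable
        if sum(1 for n in s.spanning_counts.values() if n >= min_reads) >= 2
    ]
    return VariationCensus(
        n_assessable=len(assessable),
        n_variable=len(variable),
        variable_region_ids=tuple(sorted(s.region_id for s in variable)),
    )
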