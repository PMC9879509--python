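"""Intersection of nucleotide TR regions with ORF annotations.

Classifies each region as genic / boundary / intergenic, applies the
divisible-by-three rule, and derives in-frame amino-acid tandem repeats
by translating the (frame-trimmed) repeat through the standard genetic
code.  Reverse-strand ORFs are handled by mapping the region through the
reverse complement before translation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .core_io import GenomeRecord, OrfFeature, reverse_complement
from .repeat_finder import AATR, TRRegion, primitive_root

GENIC, INTERGENIC, BOUNDARY = "genic", "intergenic", "boundary"


@dataclass(frozen=True)
class TrOrfAssignment:
    region: TRRegion
    orf: Optional[OrfFeature]
    context: str
    unit_div3: bool
    frame_offset: int = 0
    derived_aatr: Optional[AATR] = None
    anomalous_stop: bool = False


def classify_tr_context(regions: Sequence[TRRegion],
                        orfs: Sequence[OrfFeature]) -> list[TrOrfAssignment]:
    """Assign each region exactly one context.

    genic: fully contained in an ORF (ties resolved to the smallest
    containing ORF); boundary: partial overlap; intergenic: no overlap.
    """
    out: list[TrOrfAssignment] = []
    for region in regions:
        containing = [o for o in orfs
                      if o.contig_id == region.contig_id
                      and o.start <= region.start and region.end <= o.end]
        overlapping = [o for o in orfs
                       if o.contig_id == region.contig_id
                       and o.start < region.end and region.start < o.end]
        if containing:
            orf = min(containing, key=lambda o: (len(o), o.start))
            context = GENIC
        elif overlapping:
            orf = min(overlapping, key=lambda o: (len(o), o.start))
            context = BOUNDARY
        else:
            orf, context = None, INTERGENIC
        div3 = region.unit_len % 3 == 0
        frame = _frame_offset(region, orf) if orf is not None else 0
        out.append(TrOrfAssignment(region=region, orf=orf, context=context,
                                   unit_div3=div3, frame_offset=frame))
    return out


def _frame_offset(region: TRRegion, orf: OrfFeature) -> int:
    """Offset of the region start from the nearest upstream codon boundary,
    in coding-strand orientation."""
    if orf.strand == "+":
        return (region.start - orf.start) % 3
    return (orf.end - region.end) % 3


def tr_to_aatr(assignment: TrOrfAssignment,
               genome: GenomeRecord) -> Optional[AATR]:
    """Translate a genic, divisible-by-three TR region into an AATR.

    The region start is trimmed forward to the next codon boundary of its
    ORF (possibly dropping one copy); the amino-acid unit is then the
    translation of the correspondingly rotated nucleotide unit, reduced to
    its primitive root.  Returns None when the unit length is not
    divisible by three.  An in-frame stop inside the repeat yields None
    with ``anomalous_stop`` reported by :func:`derive_assignments`.
    """
    aatr, _ = _tr_to_aatr_impl(assignment, genome)
    return aatr


def _tr_to_aatr_impl(assignment: TrOrfAssignment,
                     genome: GenomeRecord) -> tuple[Optional[AATR], bool]:
    region, orf = assignment.region, assignment.orf
    if assignment.context != GENIC or orf is None:
        return None, False
    m = region.unit_len
    if m % 3 != 0:
        return None, False
    # coding-strand coordinates of the region within the ORF
    if orf.strand == "+":
        rel_start = region.start - orf.start
    else:
        rel_start = orf.end - region.end
    lead = (3 - rel_start % 3) % 3
    body_len = region.region_len - lead
    copies = body_len // m
    if copies < 1:
        return None, False
    cds_start = rel_start + lead
    if orf.strand == "+":
        nt = genome.sequence[orf.start + cds_start : orf.start + cds_start + copies * m]
    else:
        stop = orf.end - cds_start
        nt = reverse_complement(genome.sequence[stop - copies * m : stop])
    nt_unit = nt[:m]
    aa_unit = str(Seq(nt_unit).translate())
    if "*" in str(Seq(nt).translate()):
        return None, True
    root = primitive_root(aa_unit)
    factor = len(aa_unit) // len(root)
    aa_start = cds_start // 3
    aa_len = copies * m // 3
    return AATR(
        protein_id=orf.id,
        start=aa_start,
        end=aa_start + aa_len,
        unit=root,
        copies=copies * factor,
        source_region=region,
    ), False


def derive_assignments(regions: Sequence[TRRegion], orfs: Sequence[OrfFeature],
                       genome: GenomeRecord) -> list[TrOrfAssignment]:
    """classify_tr_context followed by aaTR derivation for genic regions."""
    out = []
    for asg in classify_tr_context(regions, orfs):
        aatr, stop = _tr_to_aatr_impl(asg, genome)
        out.append(TrOrfAssignment(
            region=asg.region, orf=asg.orf, context=asg.context,
            unit_div3=asg.unit_div3, frame_offset=asg.frame_offset,
            derived_aatr=aatr, anomalous_stop=stop,
        ))
    return out


def resolve_boundary(assignments: Sequence[TrOrfAssignment],
                     genic_if_majority: bool = True) -> list[TrOrfAssignment]:
    """Collapse the three-way context to the two-way split used in reports.

    Boundary regions count as genic when >=50% of the region lies inside
    the ORF (the default switch), otherwise as intergenic.
    """
    out = []
    for asg in assignments:
        if asg.context != BOUNDARY:
            out.append(asg)
            continue
        orf, region = asg.orf, asg.region
        inside = max(0, min(region.end, orf.end) - max(region.start, orf.start))
        context = GENIC if (genic_if_majority and 2 * inside >= region.region_len) \
            else INTERGENIC
        out.append(TrOrfAssignment(
            region=region, orf=orf, context=context, unit_div3=asg.unit_div3,
            frame_offset=asg.frame_offset, derived_aatr=asg.derived_aatr,
            anomalous_stop=asg.anomalous_stop,
        ))
    return out


def div3_fraction(assignments: Sequence[TrOrfAssignment],
                  context_filter: str) -> Optional[int]:
    """100 * (regions with unit length divisible by 3) / (regions in
    context), rounded to integer; None (NA) when the context is empty."""
    pool = [a for a in assignments if a.context == context_filter]
    if not pool:
        return None
    return round(100 * sum(a.unit_div3 for a in pool) / len(pool))
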