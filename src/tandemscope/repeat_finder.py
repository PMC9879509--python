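"""Perfect (mismatch-free) tandem repeat detection for nucleotide and
amino-acid sequences.

A reported region is a maximal run of a primitive unit repeated an integral
number of times, anchored at the leftmost placement of its periodic stretch.
Partial copies at the edges are reported as flanking partials, never as
copies.  Detection is exact: a single mismatch terminates a region.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .core_io import GenomeRecord, ProteinRecord, reverse_complement


@dataclass(frozen=True)
class TRRegion:
    """A maximal perfect nucleotide tandem repeat (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    unit: str
    copies: int
    left_partial: int = 0
    right_partial: int = 0
    context: str = "unassigned"

    def __post_init__(self) -> None:
        m = len(self.unit)
        if m < 1 or self.copies < 2:
            raise ValueError("unit must be non-empty and copies >= 2")
        if self.end - self.start != self.copies * m:
            raise ValueError("end - start must equal copies * unit length")
        if not (0 <= self.left_partial < m and 0 <= self.right_partial < m):
            raise ValueError("partial flank lengths must lie in [0, unit length)")

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def region_len(self) -> int:
        return self.end - self.start

    def validate(self, sequence: str) -> None:
        """Check the perfect-repeat, primitivity and maximality invariants."""
        m = len(self.unit)
        body = sequence[self.start : self.end]
        if body != self.unit * self.copies:
            raise AssertionError(f"region {self} is not unit^copies on the sequence")
        if primitive_root(self.unit) != self.unit:
            raise AssertionError(f"unit {self.unit!r} is not primitive")
        if self.start >= m and sequence[self.start - m : self.start] == self.unit:
            raise AssertionError(f"region {self} extends left by a full unit")
        if self.end + m <= len(sequence) and sequence[self.end : self.end + m] == self.unit:
            raise AssertionError(f"region {self} extends right by a full unit")


@dataclass(frozen=True)
class AATR:
    """An amino-acid tandem repeat within a protein (aa coordinates)."""

    protein_id: str
    start: int
    end: int
    unit: str
    copies: int
    source_region: Optional[TRRegion] = None

    def __post_init__(self) -> None:
        if self.end - self.start != self.copies * len(self.unit):
            raise ValueError("end - start must equal copies * unit length")

    @property
    def unit_len(self) -> int:
        return len(self.unit)


@dataclass(frozen=True)
class FinderConfig:
    """Thresholds for nucleotide and amino-acid repeat detection.

    Defaults reproduce the stringent published search: nt regions of
    >=50 nt with >=3 units and no mismatch; aa regions of >=16 aa with
    >=3 units and unit length >=3.  ``max_unit_len_nt`` bounds the period
    scan on genome-scale inputs; ``None`` scans every feasible period.
    """

    min_region_len_nt: int = 50
    min_copies: int = 3
    min_unit_len_nt: int = 1
    min_region_len_aa: int = 16
    min_unit_len_aa: int = 3
    min_distinct_chars: int = 1
    max_unit_len_nt: Optional[int] = None
    max_unit_len_aa: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("min_region_len_nt", "min_copies", "min_unit_len_nt",
                     "min_region_len_aa", "min_unit_len_aa", "min_distinct_chars"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def primitive_root(unit: str) -> str:
    """Shortest string p such that unit == p * (len(unit) // len(p)).

    Uses the KMP failure function: the candidate period is
    n - failure[n-1]; it is the primitive period iff it divides n.
    """
    n = len(unit)
    if n == 0:
        raise ValueError("unit must be non-empty")
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and unit[i] != unit[k]:
            k = fail[k - 1]
        if unit[i] == unit[k]:
            k += 1
        fail[i] = k
    p = n - fail[n - 1]
    if n % p == 0:
        return unit[:p]
    return unit


def _match_runs(arr: np.ndarray, valid: np.ndarray, m: int) -> list[tuple[int, int]]:
    """Maximal runs [i, j) of positions where arr[i] == arr[i+m], both valid."""
    eq = (arr[:-m] == arr[m:]) & valid[:-m] & valid[m:]
    if not eq.any():
        return []
    padded = np.concatenate(([False], eq, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def _scan_periodic(seq: str, *, min_region_len: int, min_copies: int,
                   min_unit_len: int, max_unit_len: Optional[int],
                   min_distinct: int, invalid_chars: str) -> list[tuple[int, int, str, int]]:
    """Shared period-scan engine.

    Returns (start, end, unit, copies) for every maximal primitive tandem
    array passing the thresholds, at the leftmost placement of its
    periodic stretch.  Positions holding ``invalid_chars`` never match,
    so no region contains them.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = np.ones(n, dtype=bool)
    for ch in invalid_chars:
        valid &= arr != ord(ch)
    cap = n // min_copies
    if max_unit_len is not None:
        cap = min(cap, max_unit_len)
    out: list[tuple[int, int, str, int]] = []
    for m in range(min_unit_len, cap + 1):
        # a run shorter than this cannot satisfy both thresholds
        min_run = max((min_copies - 1) * m, min_region_len - m)
        for i, j in _match_runs(arr, valid, m):
            if j - i < min_run:
                continue
            stretch = j - i + m
            copies = stretch // m
            if copies < min_copies or copies * m < min_region_len:
                continue
            unit = seq[i : i + m]
            if len(primitive_root(unit)) != m:
                continue
            if len(set(unit)) < min_distinct:
                continue
            out.append((i, i + copies * m, unit, copies))
    out.sort(key=lambda r: (r[0], r[1], r[2]))
    return out


def find_nt_tandem_repeats(genome: GenomeRecord,
                           cfg: FinderConfig = FinderConfig()) -> list[TRRegion]:
    """Detect every maximal perfect nucleotide TR region in a genome.

    Regions are reported on the stored strand at the leftmost maximal
    placement; the canonical unit is the rotation beginning at the region
    start.  Overlapping arrays with distinct primitive units are all
    reported; phase-shifted views of one periodic stretch are collapsed
    to the single canonical placement.
    """
    hits = _scan_periodic(
        genome.sequence,
        min_region_len=cfg.min_region_len_nt,
        min_copies=cfg.min_copies,
        min_unit_len=cfg.min_unit_len_nt,
        max_unit_len=cfg.max_unit_len_nt,
        min_distinct=cfg.min_distinct_chars,
        invalid_chars="N",
    )
    regions = []
    for start, end, unit, copies in hits:
        region = TRRegion(contig_id=genome.id, start=start, end=end,
                          unit=unit, copies=copies)
        a, b = flanking_partials(region, genome)
        regions.append(replace(region, left_partial=a, right_partial=b))
    return regions


def find_aa_tandem_repeats(protein: ProteinRecord,
                           cfg: FinderConfig = FinderConfig()) -> list[AATR]:
    """Detect amino-acid tandem repeats (>=16 aa, >=3 units by default).

    X residues are tolerated in the protein but never inside a region.
    """
    hits = _scan_periodic(
        protein.sequence,
        min_region_len=cfg.min_region_len_aa,
        min_copies=cfg.min_copies,
        min_unit_len=cfg.min_unit_len_aa,
        max_unit_len=cfg.max_unit_len_aa,
        min_distinct=cfg.min_distinct_chars,
        invalid_chars="X*",
    )
    return [
        AATR(protein_id=protein.id, start=start, end=end, unit=unit, copies=copies)
        for start, end, unit, copies in hits
    ]


def flanking_partials(region: TRRegion, genome: GenomeRecord) -> tuple[int, int]:
    """Lengths (a, b) of the partial repeats flanking a region.

    a is the maximal k < m with the k bases upstream equal to the unit's
    suffix of length k; b is the analogue downstream versus the unit's
    prefix.  Both are clipped at the contig bounds.
    """
    seq = genome.sequence
    unit, m = region.unit, region.unit_len
    a = 0
    while a < m - 1 and region.start - 1 - a >= 0 \
            and seq[region.start - 1 - a] == unit[m - 1 - a]:
        a += 1
    b = 0
    while b < m - 1 and region.end + b < len(seq) \
            and seq[region.end + b] == unit[b]:
        b += 1
    return a, b


def enumerate_phases(region: TRRegion,
                     genome: GenomeRecord) -> list[tuple[int, str]]:
    """All placements of the full-copy window inside the extended periodic
    interval, each with its rotated unit.  Count equals a + b + 1."""
    a, b = flanking_partials(region, genome)
    seq = genome.sequence
    m = region.unit_len
    return [
        (region.start + t, seq[region.start + t : region.start + t + m])
        for t in range(-a, b + 1)
    ]


def find_terminal_inverted_repeats(genome: GenomeRecord,
                                   min_len: int = 20) -> Optional[int]:
    """Length of the longest exact terminal inverted repeat, if >= min_len.

    The repeat is the longest k (capped at half the genome so the two
    copies cannot overlap) with prefix[:k] == revcomp(suffix[-k:]);
    equivalently the longest common prefix of the sequence and its
    reverse complement.  Returns None below min_len.
    """
    seq = genome.sequence
    rc = reverse_complement(seq)
    cap = len(seq) // 2
    k = 0
    while k < cap and seq[k] == rc[k]:
        k += 1
    return k if k >= min_len else None
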