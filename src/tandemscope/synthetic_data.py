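"""Synthetic linear genomes with planted tandem repeats and ground truth.

The generator emits a genome whose background matches a configured base
composition (optionally split into two replichores with opposite G/C
excess), planted ORFs with start/stop codons and no in-frame stops,
planted intergenic TRs with A-enriched units and optional partial flanks,
planted genic TRs whose units are codon-aligned and divisible by three,
read populations with whole-unit copy-number heterogeneity, and a variant
table with configurable substitution tallies inside and outside TRs.

Planted flanks always satisfy a + b < unit length, so the canonical
(leftmost) detection of a planted region keeps the planted copy number
and reports a single right partial of length a + b.  The bases adjacent
to each planted periodic stretch are forced to break the periodicity, and
the finished genome is validated by running the detector and requiring
exact agreement with the planted truth; the generation is retried with a
fresh substream on the rare collision.  All outputs are pure functions of
(config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .core_io import (GenomeRecord, OrfFeature, ProteinRecord,
                      VariantRecord, reverse_complement, write_fasta,
                      write_gff3, write_regions_tsv, write_variants_tsv)
from .repeat_finder import FinderConfig, TRRegion, find_nt_tandem_repeats, primitive_root

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: codons kept out of planted genic repeat units (stops plus the codons
#: reported absent from the real aaTR data: CGA, CGT, CGG, TTC, TGC)
EXCLUDED_UNIT_CODONS = frozenset(STOP_CODONS | {"CGA", "CGT", "CGG", "TTC", "TGC"})

_CODONS_BY_AA: dict[str, list[str]] = {}
for _c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3)):
    if _c in EXCLUDED_UNIT_CODONS:
        continue
    _CODONS_BY_AA.setdefault(str(Seq(_c).translate()), []).append(_c)


class ConfigError(ValueError):
    """Raised when a simulation config is infeasible."""


def _default_genic_aa_freqs() -> dict[str, float]:
    # enriched in P, T, E, K; W/C/F nearly absent
    freqs = {aa: 1.0 for aa in _CODONS_BY_AA}
    for aa in "PTEK":
        freqs[aa] = 5.0
    for aa in "WCF":
        freqs[aa] = 0.05
    total = sum(freqs.values())
    return {aa: w / total for aa, w in freqs.items()}


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 100_000
    background_base_freqs: tuple[float, float, float, float] = (0.384, 0.288, 0.203, 0.125)  # A,T,G,C
    n_intergenic_trs: int = 5
    n_genic_trs: int = 5
    unit_len_range_nt: tuple[int, int] = (6, 30)
    copy_range: tuple[int, int] = (3, 8)
    tr_base_freqs: tuple[float, float, float, float] = (0.484, 0.237, 0.171, 0.108)  # A,T,G,C
    partial_flank_prob: float = 0.5
    n_orfs: int = 20
    two_replichore_skew: bool = True
    skew_delta: float = 0.05
    orf_len_range: tuple[int, int] = (300, 900)
    minus_strand_prob: float = 0.25
    read_length: int = 150
    n_reads: int = 2000
    unit_variation_prob: float = 0.0
    n_variable_regions: int = 0
    min_region_len: int = 50
    min_copies: int = 3
    seed: int = 0
    genic_aa_freqs: dict[str, float] = field(default_factory=_default_genic_aa_freqs)
    tr_variant_counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("G", "A"): 14, ("C", "A"): 2, ("T", "A"): 2})
    nontr_variant_counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("G", "A"): 9, ("C", "A"): 10, ("T", "A"): 2})

    def __post_init__(self) -> None:
        for vec in (self.background_base_freqs, self.tr_base_freqs):
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ConfigError("base frequency vectors must sum to 1")
        if self.unit_len_range_nt[0] > self.unit_len_range_nt[1] \
                or self.copy_range[0] > self.copy_range[1]:
            raise ConfigError("invalid ranges")
        budget = (self.n_intergenic_trs + self.n_genic_trs) \
            * self.unit_len_range_nt[1] * self.copy_range[1] \
            + self.n_orfs * self.orf_len_range[1]
        if budget > self.genome_length:
            raise ConfigError("planted features exceed genome length")


@dataclass(frozen=True)
class PlantedTR:
    """One planted repeat at its planted placement, with context metadata."""

    region: TRRegion            # planted placement incl. planted flanks
    context: str                # genic / intergenic
    orf_id: Optional[str] = None
    aa_unit: Optional[str] = None

    def canonical(self) -> TRRegion:
        """The region as the detector's leftmost canonicalization reports it."""
        r = self.region
        ext_start = r.start - r.left_partial
        return TRRegion(
            contig_id=r.contig_id, start=ext_start,
            end=ext_start + r.copies * r.unit_len,
            unit=(r.unit[-r.left_partial:] + r.unit[:-r.left_partial]
                  if r.left_partial else r.unit),
            copies=r.copies, left_partial=0,
            right_partial=r.left_partial + r.right_partial,
            context=r.context,
        )


@dataclass
class SyntheticTruth:
    genome: GenomeRecord
    orfs: list[OrfFeature]
    proteins: list[ProteinRecord]
    planted: list[PlantedTR]
    mixtures: dict[str, dict[int, float]]     # canonical region id -> {copies: prob}
    variants: list[VariantRecord]
    variant_classes: list[str]                # parallel to variants: TR / non_TR
    replichore_boundary: Optional[int]
    config: SimulationConfig

    def canonical_regions(self) -> list[TRRegion]:
        return sorted((p.canonical() for p in self.planted),
                      key=lambda r: (r.start, r.end, r.unit))

    def validate(self) -> None:
        """Re-validate every planted record against the emitted sequence."""
        seq = self.genome.sequence
        for planted in self.planted:
            r = planted.region
            assert seq[r.start:r.end] == r.unit * r.copies, "planted body mismatch"
            planted.canonical().validate(seq)
        for orf in self.orfs:
            cds = seq[orf.start:orf.end]
            if orf.strand == "-":
                cds = reverse_complement(cds)
            aa = str(Seq(cds).translate())
            assert aa.endswith("*") and "*" not in aa[:-1], f"ORF {orf.id} has stray stop"
        for v, label in zip(self.variants, self.variant_classes):
            assert seq[v.position] == v.ref_base, "variant ref mismatch"
            in_tr = any(c.start <= v.position < c.end for c in self.canonical_regions())
            assert (label == "TR") == in_tr, "variant class mismatch"


def _region_id(region: TRRegion) -> str:
    return f"{region.contig_id}:{region.start}-{region.end}"


# ---------------------------------------------------------------------------
# generation internals


def _sample_bases(rng: np.random.Generator, n: int,
                  freqs: Sequence[float]) -> np.ndarray:
    idx = rng.choice(4, size=n, p=list(freqs))
    return np.frombuffer("ATGC".encode(), dtype=np.uint8)[idx].copy()


def _random_nonstop_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join("ATGC"[i] for i in rng.choice(4, size=3, p=(0.384, 0.288, 0.203, 0.125)))
        if codon not in STOP_CODONS:
            return codon


def _sample_intergenic_unit(rng: np.random.Generator, m: int,
                            freqs: Sequence[float]) -> str:
    for _ in range(200):
        unit = bytes(_sample_bases(rng, m, freqs)).decode()
        if primitive_root(unit) == unit:
            return unit
    raise ConfigError("could not sample a primitive unit")


def _sample_aa_unit(rng: np.random.Generator, n_aa: int,
                    aa_freqs: dict[str, float]) -> tuple[str, str]:
    """(aa unit, nt unit): both primitive, nt unit avoids excluded codons."""
    aas = sorted(aa_freqs)
    probs = np.array([aa_freqs[a] for a in aas])
    probs = probs / probs.sum()
    for _ in range(500):
        aa_unit = "".join(rng.choice(aas, size=n_aa, p=probs))
        nt_unit = "".join(
            _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in aa_unit
        )
        if primitive_root(aa_unit) == aa_unit and primitive_root(nt_unit) == nt_unit:
            return aa_unit, nt_unit
    raise ConfigError("could not sample a primitive aa unit")


def _sample_unit_and_copies(rng: np.random.Generator, cfg: SimulationConfig,
                            genic: bool) -> tuple[int, int]:
    """(unit length nt, copies) jointly satisfying the detection thresholds."""
    lo, hi = cfg.unit_len_range_nt
    if genic:
        lo = max(3, 3 * ((lo + 2) // 3))
        hi = 3 * (hi // 3)
        if lo > hi:
            raise ConfigError("unit_len_range_nt admits no length divisible by 3")
    for _ in range(500):
        m = int(rng.integers(lo, hi + 1))
        if genic:
            m = 3 * max(1, round(m / 3))
            m = min(max(m, lo), hi - hi % 3 if hi % 3 else hi)
        c_min = max(cfg.min_copies, -(-cfg.min_region_len // m))
        if c_min <= cfg.copy_range[1]:
            c = int(rng.integers(max(c_min, cfg.copy_range[0]), cfg.copy_range[1] + 1)) \
                if c_min <= cfg.copy_range[1] else c_min
            c = max(c, c_min)
            return m, c
    raise ConfigError("copy_range incompatible with min_region_len")


class _Layout:
    """Greedy non-overlapping interval placement with a safety margin."""

    def __init__(self, rng: np.random.Generator, genome_length: int,
                 margin: int = 30):
        self.rng = rng
        self.n = genome_length
        self.margin = margin
        self.occupied: list[tuple[int, int]] = []

    def place(self, length: int) -> int:
        for _ in range(2000):
            start = int(self.rng.integers(self.margin, self.n - length - self.margin))
            lo, hi = start - self.margin, start + length + self.margin
            if all(e <= lo or s >= hi for s, e in self.occupied):
                self.occupied.append((start, start + length))
                return start
        raise ConfigError("could not place a feature; genome too crowded")


def _break_periodicity(seq: bytearray, pos: int, period: int, side: str,
                       rng: np.random.Generator,
                       orf: Optional[OrfFeature]) -> None:
    """Set seq[pos] so it differs from its periodic partner, avoiding
    in-frame stop codons when pos lies inside an ORF."""
    partner = pos + period if side == "left" else pos - period
    forbidden = seq[partner]
    candidates = [b for b in b"ACGT" if b != forbidden]
    order = rng.permutation(len(candidates))
    for k in order:
        cand = candidates[int(k)]
        old = seq[pos]
        seq[pos] = cand
        if orf is None or not _makes_stop(seq, pos, orf):
            return
        seq[pos] = old
    raise ConfigError("could not break periodicity without a stop codon")


def _makes_stop(seq: bytearray, pos: int, orf: OrfFeature) -> bool:
    if orf.strand == "+":
        codon_start = orf.start + 3 * ((pos - orf.start) // 3)
        codon = seq[codon_start : codon_start + 3].decode()
    else:
        off = (orf.end - 1 - pos) // 3
        codon_end = orf.end - 3 * off
        codon = reverse_complement(seq[codon_end - 3 : codon_end].decode())
    # terminal stop codon of the ORF is legitimate
    if orf.strand == "+" and codon_start == orf.end - 3:
        return False
    if orf.strand == "-" and codon_end - 3 == orf.start:
        return False
    return codon in STOP_CODONS


def generate_genome(cfg: SimulationConfig) -> tuple[GenomeRecord, list[OrfFeature], SyntheticTruth]:
    """Build a synthetic genome with planted features and ground truth.

    Deterministic given cfg (including cfg.seed).  Internally retries with
    a derived substream when a random background collides with a planted
    repeat, which is vanishingly rare at the default composition.
    """
    last_err: Optional[Exception] = None
    for attempt in range(20):
        rng = np.random.default_rng([cfg.seed, attempt])
        try:
            truth = _generate_once(cfg, rng)
        except ConfigError:
            raise
        except _RetryGeneration as exc:
            last_err = exc
            continue
        return truth.genome, truth.orfs, truth
    raise ConfigError(f"generation failed after 20 attempts: {last_err}")


class _RetryGeneration(Exception):
    pass


def _generate_once(cfg: SimulationConfig, rng: np.random.Generator) -> SyntheticTruth:
    n = cfg.genome_length
    if cfg.two_replichore_skew:
        a, t, g, c = cfg.background_base_freqs
        d = min(cfg.skew_delta, c * 0.8)
        half = n // 2
        seq_arr = np.concatenate([
            _sample_bases(rng, half, (a, t, g + d, c - d)),
            _sample_bases(rng, n - half, (a, t, g - d, c + d)),
        ])
        boundary: Optional[int] = half
    else:
        seq_arr = _sample_bases(rng, n, cfg.background_base_freqs)
        boundary = None
    seq = bytearray(seq_arr.tobytes())

    layout = _Layout(rng, n)
    genic_params = []
    for _ in range(cfg.n_genic_trs):
        m, c = _sample_unit_and_copies(rng, cfg, genic=True)
        aa_unit, nt_unit = _sample_aa_unit(rng, m // 3, cfg.genic_aa_freqs)
        u_codons = m // 3
        a3 = int(rng.integers(1, u_codons)) \
            if u_codons > 1 and rng.random() < cfg.partial_flank_prob else 0
        b_max = u_codons - 1 - a3
        b3 = int(rng.integers(1, b_max + 1)) \
            if b_max >= 1 and rng.random() < cfg.partial_flank_prob else 0
        genic_params.append((m, c, aa_unit, nt_unit, a3, b3))

    orfs: list[OrfFeature] = []
    planted: list[PlantedTR] = []
    proteins: list[ProteinRecord] = []

    # ORFs hosting a genic TR are sized to fit their repeat block
    n_plain_orfs = max(0, cfg.n_orfs - cfg.n_genic_trs)
    for i, (m, c, aa_unit, nt_unit, a3, b3) in enumerate(genic_params):
        block_codons = a3 + c * (m // 3) + b3
        pad = int(rng.integers(20, 60))          # codons around the block
        n_codons = block_codons + 2 * pad + 2    # + start and stop codons
        strand = "-" if rng.random() < cfg.minus_strand_prob else "+"
        start = layout.place(3 * n_codons)
        orf = OrfFeature(contig_id="synthetic", start=start, end=start + 3 * n_codons,
                         strand=strand, id=f"orf_tr_{i}")
        q = int(rng.integers(2, n_codons - block_codons - 2))
        unit_codons = [nt_unit[3 * k : 3 * k + 3] for k in range(m // 3)]
        codons = ["ATG"]
        codons += [_random_nonstop_codon(rng) for _ in range(q - 1)]
        block = (unit_codons[len(unit_codons) - a3:] if a3 else []) \
            + unit_codons * c + unit_codons[:b3]
        codons += block
        codons += [_random_nonstop_codon(rng) for _ in range(n_codons - 1 - q - block_codons)]
        codons += ["TAA"]
        cds = "".join(codons)
        assert len(cds) == 3 * n_codons
        segment = cds if strand == "+" else reverse_complement(cds)
        seq[orf.start:orf.end] = segment.encode()
        # coding-space coordinates of the full-copy body
        t0 = 3 * (q + a3)
        if strand == "+":
            g_start = orf.start + t0
            region = TRRegion(contig_id="synthetic", start=g_start,
                              end=g_start + c * m, unit=nt_unit, copies=c,
                              left_partial=3 * a3, right_partial=3 * b3,
                              context="genic")
        else:
            g_end = orf.end - t0
            region = TRRegion(contig_id="synthetic", start=g_end - c * m,
                              end=g_end, unit=reverse_complement(nt_unit),
                              copies=c, left_partial=3 * b3, right_partial=3 * a3,
                              context="genic")
        ext_start = region.start - region.left_partial
        ext_end = region.end + region.right_partial
        _break_periodicity(seq, ext_start - 1, m, "left", rng, orf)
        _break_periodicity(seq, ext_end, m, "right", rng, orf)
        orfs.append(orf)
        planted.append(PlantedTR(region=region, context="genic",
                                 orf_id=orf.id, aa_unit=aa_unit))

    for i in range(n_plain_orfs):
        length = int(rng.integers(cfg.orf_len_range[0] // 3,
                                  cfg.orf_len_range[1] // 3 + 1)) * 3
        strand = "-" if rng.random() < cfg.minus_strand_prob else "+"
        start = layout.place(length)
        orf = OrfFeature(contig_id="synthetic", start=start, end=start + length,
                         strand=strand, id=f"orf_{i}")
        codons = ["ATG"] + [_random_nonstop_codon(rng)
                            for _ in range(length // 3 - 2)] + ["TAA"]
        cds = "".join(codons)
        segment = cds if strand == "+" else reverse_complement(cds)
        seq[orf.start:orf.end] = segment.encode()
        orfs.append(orf)

    for i in range(cfg.n_intergenic_trs):
        m, c = _sample_unit_and_copies(rng, cfg, genic=False)
        unit = _sample_intergenic_unit(rng, m, cfg.tr_base_freqs)
        a = int(rng.integers(1, m)) if m > 1 and rng.random() < cfg.partial_flank_prob else 0
        b_max = m - 1 - a
        b = int(rng.integers(1, b_max + 1)) \
            if b_max >= 1 and rng.random() < cfg.partial_flank_prob else 0
        ext_len = a + c * m + b
        ext_start = layout.place(ext_len + 2) + 1   # +1 leaves the break bases free
        start = ext_start + a
        body = (unit[m - a:] if a else "") + unit * c + unit[:b]
        seq[ext_start : ext_start + ext_len] = body.encode()
        region = TRRegion(contig_id="synthetic", start=start, end=start + c * m,
                          unit=unit, copies=c, left_partial=a, right_partial=b,
                          context="intergenic")
        _break_periodicity(seq, ext_start - 1, m, "left", rng, None)
        _break_periodicity(seq, ext_start + ext_len, m, "right", rng, None)
        planted.append(PlantedTR(region=region, context="intergenic"))

    genome = GenomeRecord(id="synthetic", sequence=seq.decode())

    for orf in orfs:
        cds = genome.sequence[orf.start:orf.end]
        if orf.strand == "-":
            cds = reverse_complement(cds)
        aa = str(Seq(cds).translate())
        proteins.append(ProteinRecord(id=orf.id, sequence=aa[:-1]))

    # validation: detector output must equal the planted canonical set
    cap = max(100, cfg.unit_len_range_nt[1])
    finder_cfg = FinderConfig(min_region_len_nt=cfg.min_region_len,
                              min_copies=cfg.min_copies, max_unit_len_nt=cap)
    detected = find_nt_tandem_repeats(genome, finder_cfg)
    expected = {( p.canonical().start, p.canonical().end, p.canonical().unit,
                  p.canonical().copies) for p in planted}
    got = {(r.start, r.end, r.unit, r.copies) for r in detected}
    if expected != got:
        raise _RetryGeneration(
            f"planted/detected mismatch: extra={got - expected}, missing={expected - got}")

    mixtures: dict[str, dict[int, float]] = {}
    if cfg.n_variable_regions > 0:
        if cfg.n_variable_regions > len(planted):
            raise ConfigError("more variable regions requested than planted")
        order = rng.permutation(len(planted))[: cfg.n_variable_regions]
        for idx in order:
            canon = planted[int(idx)].canonical()
            c = canon.copies
            alt = c - 1 if c - 1 >= 2 else c + 1
            mixtures[_region_id(canon)] = {
                c: 1.0 - cfg.unit_variation_prob, alt: cfg.unit_variation_prob}

    truth = SyntheticTruth(
        genome=genome, orfs=sorted(orfs, key=lambda o: o.start),
        proteins=proteins, planted=sorted(planted, key=lambda p: p.region.start),
        mixtures=mixtures, variants=[], variant_classes=[],
        replichore_boundary=boundary, config=cfg,
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# reads


def generate_reads(genome: GenomeRecord, truth: SyntheticTruth,
                   cfg: SimulationConfig) -> list[str]:
    """Uniform-start reads; reads overlapping a variable region sample the
    molecule's unit count from the region's planted mixture."""
    rng = np.random.default_rng([cfg.seed, 7919])
    n, L = len(genome), cfg.read_length
    if L > n:
        raise ConfigError("read length exceeds genome length")
    canon = {_region_id(r): r for r in truth.canonical_regions()}
    variable = [(canon[rid], truth.mixtures[rid]) for rid in sorted(truth.mixtures)]
    reads: list[str] = []
    for _ in range(cfg.n_reads):
        start = int(rng.integers(0, n - L + 1))
        hit = next((rv for rv in variable
                    if rv[0].start < start + L and start < rv[0].end + L), None)
        if hit is None:
            reads.append(genome.sequence[start : start + L])
            continue
        region, mixture = hit
        ks = sorted(mixture)
        k = int(rng.choice(ks, p=[mixture[x] for x in ks]))
        if k == region.copies:
            reads.append(genome.sequence[start : start + L])
            continue
        molecule = (genome.sequence[: region.start]
                    + region.unit * k
                    + genome.sequence[region.end :])
        start = min(start, len(molecule) - L)
        reads.append(molecule[start : start + L])
    return reads


# ---------------------------------------------------------------------------
# variants


def generate_variant_table(truth: SyntheticTruth,
                           cfg: SimulationConfig) -> list[VariantRecord]:
    """Plant ref->alt substitution observations with the configured tallies
    inside (TR) and outside (non-TR) canonical repeat regions."""
    rng = np.random.default_rng([cfg.seed, 104729])
    seq = truth.genome.sequence
    regions = truth.canonical_regions()
    in_tr = np.zeros(len(seq), dtype=bool)
    for r in regions:
        in_tr[r.start : r.end] = True
    variants: list[VariantRecord] = []
    classes: list[str] = []
    for label, counts, mask in (("TR", cfg.tr_variant_counts, in_tr),
                                ("non_TR", cfg.nontr_variant_counts, ~in_tr)):
        used: set[int] = set()
        for (ref, alt), k in sorted(counts.items()):
            candidates = [i for i in np.flatnonzero(mask).tolist()
                          if seq[i] == ref and i not in used]
            if len(candidates) < k:
                raise ConfigError(
                    f"not enough {ref} positions in the {label} class for {k} variants")
            picks = rng.choice(len(candidates), size=k, replace=False)
            for p in picks:
                pos = candidates[int(p)]
                used.add(pos)
                variants.append(VariantRecord(contig_id=truth.genome.id, position=pos,
                                              ref_base=ref, alt_base=alt, count=1))
                classes.append(label)
    truth.variants = variants
    truth.variant_classes = classes
    truth.validate()
    return variants


# ---------------------------------------------------------------------------
# emission


def emit_outputs(truth: SyntheticTruth, outdir: str | Path) -> None:
    """Write FASTA/GFF3/protein FASTA/region TSV/truth JSON for a run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([truth.genome], outdir / "genome.fa")
    write_gff3(truth.orfs, outdir / "orfs.gff3")
    write_fasta(truth.proteins, outdir / "proteins.faa")
    write_regions_tsv([p.region for p in truth.planted], outdir / "planted_regions.tsv")
    if truth.variants:
        write_variants_tsv(truth.variants, outdir / "variants.tsv")
    payload = {
        "replichore_boundary": truth.replichore_boundary,
        "mixtures": {k: {str(c): p for c, p in v.items()}
                     for k, v in truth.mixtures.items()},
        "planted": [
            {"start": p.region.start, "end": p.region.end, "unit": p.region.unit,
             "copies": p.region.copies, "left_partial": p.region.left_partial,
             "right_partial": p.region.right_partial, "context": p.context,
             "orf_id": p.orf_id, "aa_unit": p.aa_unit}
            for p in truth.planted
        ],
        "config": {
            "genome_length": truth.config.genome_length,
            "seed": truth.config.seed,
            "n_genic_trs": truth.config.n_genic_trs,
            "n_intergenic_trs": truth.config.n_intergenic_trs,
        },
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=2))
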