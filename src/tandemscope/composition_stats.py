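"""Compositional statistics: windowed nucleotide contrasts between repeat
and non-repeat DNA (Kruskal-Wallis + Benjamini-Yekutieli), codon usage
inside versus outside aaTRs, positional nucleotide frequencies, amino-acid
enrichment, and SNP base-change tallies.

The Kruskal-Wallis statistic and the Benjamini-Yekutieli step-up are
implemented directly (rank formula / harmonic-factor formula) so they can
be cross-checked against library implementations in the test suite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact, rankdata

from .core_io import DNA_BASES, GenomeRecord, VariantRecord
from .repeat_finder import AATR, TRRegion

REPEAT, NON_REPEAT = "repeat", "non_repeat"

#: Vector order of CompositionSample counts.
SAMPLE_BASE_ORDER = ("A", "T", "C", "G")

#: Report order for the per-nucleotide contrast.
TEST_BASE_ORDER = ("A", "T", "G", "C")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: TOP-IDP disorder propensity per residue (higher = more disorder
#: promoting); used only to order enrichment tables.
TOP_IDP = {
    "W": -0.884, "F": -0.697, "Y": -0.510, "I": -0.486, "M": -0.397,
    "L": -0.326, "V": -0.121, "N": 0.007, "C": 0.020, "T": 0.059,
    "A": 0.060, "G": 0.166, "R": 0.180, "D": 0.192, "H": 0.303,
    "Q": 0.318, "S": 0.341, "K": 0.586, "E": 0.736, "P": 0.987,
}

ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]


@dataclass(frozen=True)
class CompositionSample:
    """Base counts [A, T, C, G] of one fixed-width substring."""

    class_label: str
    vector: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.class_label not in (REPEAT, NON_REPEAT):
            raise ValueError(f"bad class label {self.class_label!r}")
        if any(v < 0 for v in self.vector):
            raise ValueError("negative base count")

    @property
    def width(self) -> int:
        return sum(self.vector)


@dataclass(frozen=True)
class CompositionTest:
    nucleotide: str
    H: float
    p_raw: float
    p_adj: float
    mean_repeat: float
    mean_nonrepeat: float


def partition_substrings(genome: GenomeRecord, regions: Sequence[TRRegion],
                         width: int = 50) -> list[CompositionSample]:
    """Cut repeat and non-repeat segments into consecutive width-bp
    substrings (remainders dropped) and count bases per substring.

    Substrings containing N are excluded.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    n = len(genome)
    intervals = sorted((r.start, r.end) for r in regions)
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    segments: list[tuple[int, int, str]] = []
    prev = 0
    for s, e in merged:
        if s > prev:
            segments.append((prev, s, NON_REPEAT))
        segments.append((s, e, REPEAT))
        prev = e
    if prev < n:
        segments.append((prev, n, NON_REPEAT))
    samples: list[CompositionSample] = []
    for s, e, label in segments:
        for i in range(s, e - width + 1, width):
            sub = genome.sequence[i : i + width]
            if "N" in sub:
                continue
            vec = tuple(sub.count(b) for b in SAMPLE_BASE_ORDER)
            samples.append(CompositionSample(class_label=label, vector=vec))
    return samples


def kruskal_wallis(group1: Sequence[float],
                   group2: Sequence[float]) -> tuple[float, float]:
    """Two-group Kruskal-Wallis H with tie correction and the chi-square
    p-value (df = 1).  All-identical data gives H = 0, p = 1."""
    if not len(group1) or not len(group2):
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([np.asarray(group1, float), np.asarray(group2, float)])
    n1, n = len(group1), len(pooled)
    ranks = rankdata(pooled)
    r1, r2 = ranks[:n1], ranks[n1:]
    h = 12.0 / (n * (n + 1)) * (r1.sum() ** 2 / n1 + r2.sum() ** 2 / (n - n1)) \
        - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n**3 - n)
    if denom == 0.0:
        return 0.0, 1.0
    h /= denom
    return float(h), float(chi2.sf(h, df=1))


def benjamini_yekutieli(p_values: Sequence[float]) -> list[float]:
    """BY step-up adjustment: adj_(i) = min_{j >= i} p_(j) * m * c(m) / j,
    capped at 1, with c(m) the m-th harmonic number; order preserved."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m * c_m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def tr_composition_test(genome: GenomeRecord, regions: Sequence[TRRegion],
                        width: int = 50) -> list[CompositionTest]:
    """Per-nucleotide Kruskal-Wallis contrast of repeat vs non-repeat
    substring composition, BY-corrected across the four tests.  Class
    means are reported as percentages of the substring width."""
    samples = partition_substrings(genome, regions, width=width)
    rep = [s.vector for s in samples if s.class_label == REPEAT]
    non = [s.vector for s in samples if s.class_label == NON_REPEAT]
    if len(rep) < 2 or len(non) < 2:
        warnings.warn("a class has fewer than 2 substrings; tests skipped")
        return []
    rep_arr, non_arr = np.array(rep, float), np.array(non, float)
    results = []
    p_raws = []
    for base in TEST_BASE_ORDER:
        idx = SAMPLE_BASE_ORDER.index(base)
        h, p = kruskal_wallis(rep_arr[:, idx], non_arr[:, idx])
        results.append((base, h, p,
                        100 * rep_arr[:, idx].mean() / width,
                        100 * non_arr[:, idx].mean() / width))
        p_raws.append(p)
    p_adj = benjamini_yekutieli(p_raws)
    return [
        CompositionTest(nucleotide=b, H=h, p_raw=p, p_adj=pa,
                        mean_repeat=mr, mean_nonrepeat=mn)
        for (b, h, p, mr, mn), pa in zip(results, p_adj)
    ]


def codon_usage(orf_seqs: Sequence[str],
                aatr_intervals: Sequence[Sequence[tuple[int, int]]],
                test: str = "fisher") -> pd.DataFrame:
    """Codon counts/frequencies inside aaTR codons versus all other codons.

    ``aatr_intervals[i]`` lists codon-index intervals (half-open) of ORF i
    that belong to aaTRs.  The ratio column is freq_in / freq_out with 0
    when a codon is absent inside and +inf when absent outside; per-codon
    enrichment p-values come from a two-sided Fisher exact test (or a
    G-test) on the 2x2 count table, BY-corrected across the 64 codons.
    """
    count_in: dict[str, int] = {c: 0 for c in ALL_CODONS}
    count_out: dict[str, int] = {c: 0 for c in ALL_CODONS}
    for seq, intervals in zip(orf_seqs, aatr_intervals):
        if len(seq) % 3 != 0:
            raise ValueError("coding sequence length not divisible by 3")
        n_codons = len(seq) // 3
        inside = np.zeros(n_codons, dtype=bool)
        for s, e in intervals:
            if not (0 <= s <= e <= n_codons):
                raise ValueError(f"codon interval ({s}, {e}) not codon-aligned")
            inside[s:e] = True
        for i in range(n_codons):
            codon = seq[3 * i : 3 * i + 3]
            if codon not in count_in:
                continue  # ambiguous bases
            (count_in if inside[i] else count_out)[codon] += 1
    total_in = sum(count_in.values())
    total_out = sum(count_out.values())
    rows = []
    for codon in ALL_CODONS:
        ci, co = count_in[codon], count_out[codon]
        fi = ci / total_in if total_in else 0.0
        fo = co / total_out if total_out else 0.0
        if fo == 0:
            ratio = np.inf if fi > 0 else np.nan
        else:
            ratio = fi / fo
        p = _count_test(ci, total_in - ci, co, total_out - co, test)
        rows.append((codon, ci, co, fi, fo, ratio, p))
    df = pd.DataFrame(rows, columns=["codon", "count_in_aaTR", "count_outside",
                                     "freq_in", "freq_out", "ratio", "p_raw"])
    df["p_adj"] = benjamini_yekutieli(df["p_raw"].tolist())
    return df.set_index("codon")


def _count_test(a: int, b: int, c: int, d: int, test: str) -> float:
    if test == "fisher":
        return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if test == "g":
        obs = np.array([[a, b], [c, d]], float)
        if obs.sum() == 0 or (obs.sum(0) == 0).any() or (obs.sum(1) == 0).any():
            return 1.0
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
        return float(chi2.sf(2 * terms.sum(), df=1))
    raise ValueError(f"unknown test {test!r}")


def absent_codons(table: pd.DataFrame) -> list[str]:
    """Codons never seen inside aaTRs but present outside."""
    mask = (table["count_in_aaTR"] == 0) & (table["count_outside"] > 0)
    return table.index[mask].tolist()


def positional_nt_frequency(codons_in: Sequence[str],
                            codons_out: Sequence[str]) -> dict[str, pd.DataFrame]:
    """Per-class 4x3 tables: fraction of each base at codon positions 1-3."""
    if not codons_in or not codons_out:
        raise ValueError("codon lists must be non-empty")
    out = {}
    for label, codons in (("aaTR", codons_in), ("non_aaTR", codons_out)):
        table = pd.DataFrame(0.0, index=list(DNA_BASES), columns=[1, 2, 3])
        for codon in codons:
            for pos, base in enumerate(codon, start=1):
                table.loc[base, pos] += 1
        out[label] = table / len(codons)
    return out


def aa_enrichment(aatrs: Sequence[AATR],
                  proteome: Sequence) -> pd.DataFrame:
    """Per-residue frequency in concatenated aaTR regions divided by the
    frequency in all proteins, ordered by descending disorder propensity.

    Residues absent from the proteome get ratio NaN.
    """
    if not aatrs or not proteome:
        raise ValueError("aatrs and proteome must be non-empty")
    in_seq = "".join(a.unit * a.copies for a in aatrs)
    all_seq = "".join(p.sequence for p in proteome)
    order = sorted(TOP_IDP, key=lambda aa: -TOP_IDP[aa])
    rows = []
    for aa in order:
        fi = in_seq.count(aa) / len(in_seq)
        fa = all_seq.count(aa) / len(all_seq)
        ratio = fi / fa if fa > 0 else np.nan
        rows.append((aa, TOP_IDP[aa], fi, fa, ratio))
    return pd.DataFrame(
        rows, columns=["aa", "disorder_propensity", "freq_in_aaTR",
                       "freq_proteome", "ratio"]
    ).set_index("aa")


def snp_bias_summary(variants: Sequence[VariantRecord],
                     regions: Sequence[TRRegion],
                     contig_lengths: Optional[Mapping[str, int]] = None,
                     ) -> dict[str, pd.DataFrame]:
    """4x4 ref->alt substitution-count matrices for the TR and non-TR
    classes (rows = ref, columns = alt), counts weighted by the variant's
    observation count."""
    mats = {
        "TR": pd.DataFrame(0, index=list(DNA_BASES), columns=list(DNA_BASES)),
        "non_TR": pd.DataFrame(0, index=list(DNA_BASES), columns=list(DNA_BASES)),
    }
    by_contig: dict[str, list[TRRegion]] = {}
    for r in regions:
        by_contig.setdefault(r.contig_id, []).append(r)
    for v in variants:
        if contig_lengths is not None:
            length = contig_lengths.get(v.contig_id)
            if length is not None and v.position >= length:
                warnings.warn(f"variant at {v.contig_id}:{v.position} out of bounds")
                continue
        in_tr = any(r.start <= v.position < r.end
                    for r in by_contig.get(v.contig_id, ()))
        mats["TR" if in_tr else "non_TR"].loc[v.ref_base, v.alt_base] += v.count
    return mats


def substitution_fraction(matrix: pd.DataFrame, ref: str, alt: str) -> float:
    """Fraction of all substitutions in the matrix that are ref->alt."""
    total = matrix.to_numpy().sum()
    if total == 0:
        return float("nan")
    return float(matrix.loc[ref, alt] / total)
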