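"""Domain records and readers/writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere.  GFF3 (1-based,
inclusive) and the 1-based variant TSV are converted at the I/O boundary;
BED shares the internal convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

NT_ALPHABET = frozenset("ACGTN")
DNA_BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FASTA_WRAP = 60


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide sequence record; topology defaults to linear."""

    id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - NT_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)
        if self.topology not in ("linear", "circular"):
            raise FormatError(f"record {self.id!r}: bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence record (X tolerated, stops stripped upstream)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfFeature:
    """An ORF/CDS interval in internal coordinates (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    strand: str
    id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise FormatError(
                f"ORF {self.id!r}: bad interval [{self.start}, {self.end})"
            )
        if self.end - self.start < 6:
            raise FormatError(f"ORF {self.id!r}: shorter than 6 nt")
        if self.strand not in ("+", "-"):
            raise FormatError(f"ORF {self.id!r}: unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant with an observation count (0-based position)."""

    contig_id: str
    position: int
    ref_base: str
    alt_base: str
    count: int = 1

    def __post_init__(self) -> None:
        for base, name in ((self.ref_base, "ref"), (self.alt_base, "alt")):
            if base not in DNA_BASES:
                raise FormatError(f"variant at {self.position}: bad {name} {base!r}")
        if self.ref_base == self.alt_base:
            raise FormatError(f"variant at {self.position}: ref == alt")
        if self.position < 0 or self.count < 1:
            raise FormatError(f"variant at {self.position}: bad position/count")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _iter_fasta(handle: io.TextIOBase) -> Iterable[tuple[str, str]]:
    header = None
    chunks: list[str] = []
    for line in handle:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks)
            header = line[1:].split()[0]
            chunks = []
        else:
            if header is None:
                raise FormatError("FASTA: sequence data before first header")
            chunks.append(line.strip())
    if header is not None:
        yield header, "".join(chunks)


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read nucleotide FASTA into GenomeRecords (uppercased; U rejected)."""
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for name, seq in _iter_fasta(fh):
            if name in seen:
                raise FormatError(f"duplicate FASTA id {name!r}")
            seen.add(name)
            if "U" in seq.upper():
                raise FormatError(f"record {name!r}: RNA base U not accepted")
            records.append(GenomeRecord(id=name, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for name, seq in _iter_fasta(fh):
            if name in seen:
                raise FormatError(f"duplicate FASTA id {name!r}")
            seen.add(name)
            records.append(ProteinRecord(id=name, sequence=seq.rstrip("*")))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Sequence[GenomeRecord | ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


def read_reads(path: str | Path) -> list[str]:
    """Read sequences from FASTA or FASTQ (qualities ignored)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        seqs = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                if i % 4 == 1:
                    seqs.append(line.strip().upper())
        return seqs
    with open(path) as fh:
        return [seq for _, seq in _iter_fasta(fh)]


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> list[OrfFeature]:
    """Read CDS/gene lines from a GFF3 file into 0-based half-open OrfFeatures."""
    feats: list[OrfFeature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 GFF3 columns")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in ("CDS", "gene"):
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise FormatError(f"{path}:{ln}: end < start")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{ln}: unknown strand {strand!r}")
            fid = f"{contig}:{start_i}-{end_i}"
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    fid = kv[3:]
                    break
            feats.append(
                OrfFeature(contig_id=contig, start=start_i - 1, end=end_i,
                           strand=strand, id=fid)
            )
    return feats


def write_gff3(orfs: Sequence[OrfFeature], path: str | Path,
               source: str = "tandemscope") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in orfs:
            fh.write(
                "\t".join(
                    [orf.contig_id, source, "CDS", str(orf.start + 1), str(orf.end),
                     ".", orf.strand, "0", f"ID={orf.id}"]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TR region BED/TSV (the region type lives in repeat_finder; duck-typed here)

REGION_TSV_COLUMNS = (
    "contig_id", "start", "end", "unit", "copies",
    "left_partial", "right_partial", "context",
)


def write_regions_bed(regions: Sequence, path: str | Path) -> None:
    """Write TR regions as BED6 plus a full-field TSV sidecar (<path>.tsv)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# BED6: chrom start end unit copies strand\n")
        for r in regions:
            fh.write(
                f"{r.contig_id}\t{r.start}\t{r.end}\t{r.unit}\t{r.copies}\t+\n"
            )
    write_regions_tsv(regions, path.with_suffix(path.suffix + ".tsv"))


def write_regions_tsv(regions: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REGION_TSV_COLUMNS) + "\n")
        for r in regions:
            fh.write(
                "\t".join(
                    str(v) for v in (
                        r.contig_id, r.start, r.end, r.unit, r.copies,
                        r.left_partial, r.right_partial, r.context,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Variant table TSV (positions 1-based in file)


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    variants: list[VariantRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("contig"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected >=4 columns")
            contig, pos, ref, alt = parts[:4]
            count = int(parts[4]) if len(parts) > 4 else 1
            variants.append(
                VariantRecord(contig_id=contig, position=int(pos) - 1,
                              ref_base=ref.upper(), alt_base=alt.upper(), count=count)
            )
    return variants


def write_variants_tsv(variants: Sequence[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\tcount\n")
        for v in variants:
            fh.write(
                f"{v.contig_id}\t{v.position + 1}\t{v.ref_base}\t{v.alt_base}\t{v.count}\n"
            )
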