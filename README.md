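# tandemscope

Detection and characterization of perfect tandem repeats in linear
genomes. The package finds maximal, mismatch-free nucleotide tandem
repeat (TR) regions and amino-acid tandem repeats (aaTRs), characterizes
their flanking partial repeats and phase alternatives, intersects TRs
with ORF annotations (divisible-by-three rule, in-frame translation),
profiles GC skew and replichore structure, runs compositional statistics
(Kruskal–Wallis contrasts with Benjamini–Yekutieli FDR, codon usage,
amino-acid enrichment, SNP tallies), clusters aaTR units by tripled-unit
alignment distance, quantifies within-population unit-number variation
from spanning reads, and generates fully ground-truthed synthetic
genomes so every stage is testable offline.

## Layout

| module | role |
| --- | --- |
| `core_io` | FASTA/FASTQ/GFF3/BED/TSV readers and writers; domain records; all internal coordinates 0-based half-open |
| `repeat_finder` | perfect nucleotide/amino-acid TR detection (primitive units, leftmost maximal placement), flanking partials, phase enumeration, terminal inverted repeats |
| `aatr_mapper` | TR × ORF context classification, divisible-by-3 rule, in-frame aaTR derivation (both strands) |
| `skew_profiler` | GC skew, cumulative skew, origin/terminus prediction, repeat-local GC symmetry profile |
| `composition_stats` | 50-bp substring partition, Kruskal–Wallis + Benjamini–Yekutieli, codon usage and absent codons, positional nucleotide frequency, amino-acid enrichment (disorder-propensity ordered), SNP substitution matrices |
| `aatr_clustering` | tripled-unit identity-distance matrix, average-linkage clustering, ≥10 % residue naming rule, Newick export |
| `population_variation` | exact-anchor spanning-read unit counting, variable-region census |
| `synthetic_data` | seeded generator for genomes/ORFs/proteins/reads/variant tables with machine-readable planted truth |
| `report` | per-genome summary rows with defined derived columns, average/sum aggregation |
| `cli` | `tandemscope` command (scan / aatr / simulate / run / report) |

## CLI

```bash
# detect nucleotide TRs (defaults: region >= 50 nt, >= 3 units, no mismatch)
tandemscope scan --fasta genome.fa --out regions.tsv --bed regions.bed

# detect amino-acid TRs (defaults: region >= 16 aa, >= 3 units, unit >= 3 aa)
tandemscope aatr --fasta proteins.faa --out aatrs.tsv

# synthetic genome with planted repeats and ground truth
tandemscope simulate --seed 7 --outdir sim/ --reads --variants

# full pipeline on one genome
tandemscope run --fasta g.fa --gff g.gff3 --proteins p.faa \
    [--reads r.fastq] [--variants v.tsv] --outdir out/

# re-derive the summary table from stage outputs
tandemscope report --regions out/regions.tsv --fasta g.fa \
    --gff g.gff3 --proteins p.faa --out summary.tsv
```

`run` writes `regions.tsv`/`regions.bed`, `assignments.tsv`,
`aatrs.tsv`, `clusters.tsv`, `skew_<contig>.tsv`,
`composition_<contig>.tsv`, `summary.tsv` and, when reads/variants are
given, `variation.tsv` and `snp_bias.tsv`.

## Conventions

- Coordinates are 0-based half-open internally; GFF3 converts at the
  I/O boundary; BED matches the internal convention.
- A reported TR region is the leftmost placement of its maximal periodic
  stretch; the canonical unit is the rotation starting at the region
  start, always primitive. Partial trailing repeats are reported as
  flanking partials, never as copies, so `enumerate_phases` returns
  exactly `left_partial + right_partial + 1` placements.
- Detection is strand-symmetric for direct repeats and therefore runs on
  the stored strand only.
- N (and X in proteins) never occurs inside a reported region.
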