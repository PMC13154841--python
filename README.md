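# circkit

Toolkit for benchmarking and quality-controlling the detection of circular
DNA and RNA elements — eccDNA (extrachromosomal circular DNA) and circRNA —
from short-read sequencing data.

Detection tools for circular elements disagree with each other to a striking
degree, and on biological data there is no ground truth to arbitrate.
`circkit` addresses both halves of that problem:

* **With ground truth (simulation).** A paired-end read simulator generates
  reads from circular templates — split reads that cross the circular
  junction (CJ), discordant pairs that span it, concordant pairs that don't —
  together with a truth BED, so precision, recall and *F*-score of any
  detection tool can be measured. Filtering strategies (split-read support,
  overlap deduplication) and multi-tool combination strategies (*Union*,
  *Intersect*, *Unique*, *Double*, and the *Rosette* consensus: circles seen
  by ≥ 2 of ≥ 3 tools) operate on the tools' BED outputs.
* **Without ground truth (biological data).** The ΔCJ junction-imbalance
  statistic: reads supporting a genuine junction should fall on its left and
  right side at equal rates, so for effective (MAPQ-weighted,
  mappability-corrected) side counts k_L and k_R with N = k_L + k_R,

      ΔCJ = |k_L − k_R| / N

  is near 0 for well-supported circles and 1 for fully one-sided — typically
  artifactual — calls. Significance comes from a two-sided binomial tail
  (expected side probability p_L = M_L / (M_L + M_R) from a mappability
  track, 0.5 under ideal mappability), with Benjamini–Hochberg correction
  across the circle set. Solving 2(N+1)·0.5^N < 0.05 shows N ≥ 9 junction
  reads are needed before a one-sided circle can even reach significance,
  which motivates the cohort quality metrics: proportion of circles with
  N ≥ 9, mean/median ΔCJ among them, and proportion significantly skewed.

## Worked example

Simulate 50 circles at ×30 coverage from a 500-kb reference and score a
degraded copy of the truth (40 of the 50 circles shifted by up to ±10 bp,
plus 10 decoys) against it:

```bash
circkit simulate --fasta ref.fa --n-circles 50 --coverage 30 --seed 1 --out sim
# -> sim/circular_R1.fastq, sim/circular_R2.fastq, sim/truth.bed, sim/manifest.txt
circkit bench --pred pred.bed --truth sim/truth.bed --threshold 20
```

```
tp	fp	fn	precision	recall	f_score	offset_ratio
40	10	10	0.8	0.8	0.8	0.0
```

Precision counts predictions matching a truth circle with both junction
coordinates within 20 bp (one-to-one matching, so duplicate predictions
don't inflate it); `offset_ratio` is the fraction of those matches accurate
to ≤ 1 bp — 0 here because every prediction was shifted.

The ΔCJ statistic on two circles, one with balanced junction support
(22 | 22 reads at MAPQ 60) and one fully one-sided (28 | 0):

```
chrom:interval      k_L k_R ΔCJ  p         p_adj     significant
chr1:1000-5000      22  22  0.0  1         1         False
chr1:10000-14000    28  0   1.0  7.45e-09  1.49e-08  True
```

The balanced circle gets p = 1 (an even split is never evidence of skew);
the one-sided circle is flagged as significantly skewed.

Per-tool BED files can be filtered and combined from the same CLI:

```bash
circkit filter toolA.bed --strategy both --min-split 2 --out toolA.filt.bed
circkit combine --strategy rosette toolA.bed toolB.bed toolC.bed --out rosette.bed
```

## Layout

| module | contents |
| --- | --- |
| `circkit.model` | `Circle`, 20-bp endpoint matching, cross-tool clustering |
| `circkit.simulate` | coordinates/reads/join simulator stages, Kimura mutation model |
| `circkit.filters` | split-read, duplicate-overlap and composed filters |
| `circkit.combine` | union / rosette / intersect / double / unique strategies |
| `circkit.metrics` | precision/recall/F, offset ratio, length KS, Yates χ² |
| `circkit.deltacj` | ΔCJ, binomial tails, BH correction, cohort metrics |
| `circkit.annotate` | RepeatMasker/GFF3 junction annotation, stratified benchmarks |
| `circkit.io` | BED/FASTA/FASTQ/manifest I/O, BAM/bigWig adapters, fixtures |
| `circkit.cli` | `circkit` command with one subcommand per stage |

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
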