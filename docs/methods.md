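# Methods

## Circle identity and clustering

All coordinates are 0-based half-open (BED). Two circles are *the same*
when they lie on the same reference sequence and both junction coordinates
agree within a threshold T (default 20 bp). We apply T per endpoint — the
strictest reading consistent with comparing circular-junction coordinates —
rather than to a midpoint distance or reciprocal overlap.

Endpoint matching is not transitive, so cross-tool clustering is
representative-anchored rather than transitive-closure: circles are
processed sorted by (chrom, start, end, tool), each joins the first cluster
whose *representative* it matches, else seeds a new cluster. The
representative is the member with the most split reads (ties: longest, then
smallest coordinates). Anchoring bounds the within-cluster spread to T;
transitive chaining could merge circles arbitrarily far apart. Cluster
support counts distinct tools, not circle instances, so a tool reporting
two near-duplicates contributes support 1.

## Simulator

The simulator emulates paired-end short-read sequencing of circular
molecules plus a linear background, in three stages (coordinates, reads,
join).

**Coordinates.** A chromosome is chosen with probability proportional to
its length among chromosomes long enough to host a circle; the circle
length is drawn from the configured distribution by rejection until it fits
(clipping would pile mass at the bounds); the start is then uniform over
admissible positions. Supported length models: uniform on
[min_len, max_len], and lognormal `loc + scale·exp(s·Z)` truncated to the
same range. Defaults follow common eccDNA/circRNA study settings: s = 1,
loc = 0, scale = 1000 (untruncated median 1 kb), lengths 175–10,000 bp.

**Reads.** The read-pair count per molecule inverts the coverage identity
`coverage = n_pairs · read_length · 2 / molecule_length`, taking the
ceiling, so every molecule gets ≥ 1 pair and realized coverage is never
below the request (relative excess ≤ read_length·2 / (coverage·length)).
Fragments of `insert_length` start uniformly on the circularized template
and wrap around the junction as often as needed (fragments longer than the
circle wrap multiple times). Read 1 is the first `read_length` bases of the
fragment, read 2 the reverse complement of its last `read_length` bases.
Truth class per pair: *split* if either read internally crosses a junction,
else *discordant* if a junction lies within the fragment between the mates,
else *concordant*; classification is per pair with split taking precedence.
An enrichment option forces a chosen fraction of fragment starts into the
window one insert length upstream of the junction (the window within which
a fragment can still reach the junction); the junction-read fraction is
monotone in that knob. Linear background fragments start uniformly on
[0, region_length − insert_length], so all pairs are concordant.

Defaults mirror standard short-read settings: read length 150 bp, insert
500 bp, sequencing error 0.001/base, mutation rate 0.01/base.

**Noise model.** Biological divergence is applied once per molecule with
the Kimura two-parameter substitution model: a hit base undergoes a
transition (A↔G, C↔T) with probability κ/(κ+2) and each transversion with
1/(κ+2); κ defaults to 2 (transitions twice as likely as either
transversion), and `N` bases are never mutated. Sequencing error is applied
independently per read as substitution to a uniformly random different
base. Base qualities are constant Q40 ("I"): the noise model operates on
sequence, not quality, and downstream consumers here ignore qualities.
Indels, quality profiles, amplification bias and long reads are out of
scope.

**Reproducibility.** All randomness flows through one `numpy` Generator;
a fixed seed gives byte-identical FASTQ/BED output. The truth class is
encoded in read names (`moleculeID|pairIndex|class`) so evaluation needs no
side files.

What the simulator does *not* emulate: chromatin- or
transcription-associated placement bias of real eccDNA/circRNA, GC and
amplification bias, chimeric artifacts, or aligner behavior. Passing
benchmarks on simulated data therefore demonstrate correctness of the
measurement pipeline, not real-data performance of any detection tool.

## Filtering and combination

`filter_split` keeps circles with ≥ 2 split reads (configurable); circles
lacking split information pass unchanged, since for tools that never report
split counts the filter is inapplicable rather than failed. Whether missing
counts should instead drop circles is genuinely open; we chose retention to
keep the filter conservative for such tools. `filter_duplicates` removes
same-chromosome overlaps (≥ 1 shared base) by a greedy priority sweep —
most split reads, then longest, then smallest coordinates — which is
deterministic, idempotent, and reduces to the stated pairwise rule on
chains of mutually overlapping circles. `filter_both` composes split-first,
then duplicates. Note that with mixed present/absent split counts the
composition can retain *more* circles than duplicate removal alone (a
dropped low-support circle no longer shadows its overlaps); with complete
split information it cannot.

Combination strategies select clusters by support s out of n tools: union
s ≥ 1, unique s = 1, intersect s = n, double 2 ≤ s < n, rosette s ≥ 2 with
n ≥ 3 enforced. Downstream consumers receive the cluster representative's
coordinates.

## Benchmark metrics

TP/FP/FN counting uses one-to-one greedy matching: candidate
prediction–truth pairs within the threshold are consumed nearest-start
first (ties by end offset), so several near-duplicate predictions of one
truth circle count one TP and the rest FP. Precision, recall and F follow
the standard formulas, reported as 0 in degenerate cases (no predictions,
or P + R = 0). The offset ratio divides matches exact to ≤ 1 bp on both
endpoints by all matches at the full threshold — we read "maximum number
detected" as the match count at the default threshold, the natural
denominator for a coordinate-precision measure. Length distributions are
compared with a two-sample Kolmogorov–Smirnov test restricted to a length
range (full 175–10,000 bp, or 175–1,000 bp for short circles); histogram
smoothing is a plotting concern only and never feeds the test. The 2×2
chi-square uses the Yates continuity correction with the |O−E|−0.5 term
clamped at zero; scipy's implementation serves as an independent
cross-check in the tests.

## ΔCJ junction-imbalance statistic

Reads are collected in windows extending N_offset = 20 nt up- and
downstream of each junction coordinate (clipped at chromosome bounds).
Each unique read contributes its probability of correct alignment,
w_i = 1 − 10^(−MAPQ_i/10); the per-side sums are rounded up, so any
strictly positive support yields an integer count ≥ 1 while an empty side
stays 0. A read appearing in both windows cannot be double-counted: it is
assigned to the side its alignment overlaps more, and exact ties are
side-uninformative and contribute to neither (defining N as the union of
window reads while summing weights per window would otherwise count such
reads twice).

Expected side probabilities come from mean mappability over the 30-nt
regions immediately inside the circle at each boundary:
p_L = M_L/(M_L + M_R). Circles shorter than 60 bp use the whole span for
both regions; missing track data (or M_L = M_R = 0) falls back to
p_L = 0.5 and is flagged in the output.

Under ideal mappability the doubled symmetric tail is
p = 2·0.5^N·Σ_{i≤k} C(N,i) with k = min(k_L, k_R). At the even-N midpoint
k = N/2 the central term is double-counted and the sum can exceed 1 (1.3125
at N = 6, k = 3), so the probability is set to exactly 1 there — a
perfectly balanced junction is never evidence of skew. With unequal
mappability the tail is evaluated on the *deficit* side — the side whose
observed count falls below its expectation — doubled and capped at 1;
applied to the surplus side the printed doubling identity would exceed 1.
At p_L = 0.5 this reduces exactly to the symmetric tail (verified against
exhaustive enumeration of all 2^N assignments for N ≤ 12). Degenerate
p_L ∈ {0, 1} with reads on the impossible side yields p = 0.

p-values are Benjamini–Hochberg adjusted; the family is one invocation
(one result set per tool/filter/combination), matching per-dataset
correction. Circles with N = 0 have undefined ΔCJ and are excluded from
the family. Cohort quality metrics: proportion of circles with N ≥ 9
(the smallest integer where a fully one-sided circle can reach α = 0.05,
from 2(N+1)·0.5^N < α; continuous bound 8.58, and 11.25 → N ≥ 12 at
α = 0.01), mean and median ΔCJ over those circles, and the proportion with
p_adj < 0.05. ΔΔCJ between two cohorts is the difference of their mean ΔCJ
(reference minus other).

## Annotation

Repeat classes (LINE, SINE, DNA, satellite, other; Ø for non-repetitive)
come from RepeatMasker `.out` intervals (1-based inclusive, converted) or a
BED with class labels. RepeatMasker intervals rarely overlap; when they do,
the fixed priority LINE > SINE > DNA > satellite > other resolves the label.
Genomic classes cascade in tiers: 3′-UTR / 5′-UTR / other (start codon,
stop codon, selenocysteine), then exon, then intron (explicit features or
derived per transcript from the exon structure), then intergenic. A circle
is classified by its start-junction coordinate, with the end-junction class
reported alongside; stratified benchmarks bucket each truth circle's TP/FN
by its class, unmatched predictions' FPs by their own class, and omit
classes without truth circles (recall is undefined there).

## Numerical and scale choices

Binomial tails use exact integer binomial sums (symmetric case) and scipy's
binomial CDF (mappability-adjusted case); the minimum-N equation is solved
by bisection to 1e-6. Ceiling of weighted sums subtracts 1e-9 first to
absorb float accumulation noise. The test suite exercises the simulator at
2 Mb / 200 circles / ×30 coverage and the distributional checks at 10,000
samples — sizes at which every sampling-error assertion has wide margins
while the whole suite runs in well under a minute; the balanced-junction
ΔCJ fixture uses 100 reads per junction, a well-covered junction depth
comfortably above the N ≥ 9 detectability threshold. All stochastic tests
are seeded and deterministic.

## Known limitations

* The simulator's truth classes describe template geometry, not aligner
  output; a real aligner may map split reads differently.
* Representative-anchored clustering depends on processing order for
  pathological inputs (many circles exactly T apart); the sorted order
  makes the result deterministic but not unique in principle.
* The ΔCJ deficit-side tail and the both-windows read rule are choices
  among several defensible conventions; both are documented above and
  isolated in single functions.
* Transcriptome (circRNA) simulation runs the identical machinery on
  transcript FASTA with truth in transcript coordinates; projection to
  genome coordinates is not implemented.
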