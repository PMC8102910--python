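# Methods

## Sequence scanning

All coordinates are 1-based and inclusive, CDS-relative; codon *k* spans
nucleotides 3k−2..3k. Protein FASTA records are upper-cased and a trailing
`*` stop marker is stripped before scanning.

**Net charge.** The charge of a 30-residue window is (#K + #R) − (#D + #E);
every other residue contributes 0 and the free amino/carboxyl termini are
ignored. This simplified scheme is equivalent, for screening purposes, to
a per-residue pKa calculation at physiological pH. One value is emitted
per window start 1..L−29; the maximum is reported with the earliest start
on ties. Proteins shorter than the window are excluded from the
net-charge category with a logged warning rather than scanned with a
partial window, which would silently change the meaning of the +12
threshold.

**K/R windows and runs.** Category (a) reports every 10-residue window
holding ≥ 8 K/R (threshold configurable; 6-in-10 is the variant used to
rank the longest basic regions). Overlapping or touching qualifying
windows are additionally unioned into maximal regions whose length is
reported — this union-of-window-spans rule is the package's operational
definition of a "polybasic region length"; the raw window starts are kept
alongside. Category (b) reports maximal runs of consecutive K/R of
length ≥ 6.

**Poly(A) and ICPs.** Category (c) reports maximal adenine runs ≥ 10 nt
in the CDS. Inhibitory codon pairs are matched strictly in frame 0 of the
annotated CDS — a pair at codons (k, k+1), never an arbitrary hexamer.
Only CGA-CGA and CGA-CCG ship as defaults; the full published list is
longer and must be supplied by the user. A CDS whose length is not a
multiple of 3 is truncated to the last full codon with a warning.

Classification produces per-gene booleans for (a)–(d), the 15 disjoint
Venn region counts (which sum to the union), and an `icp` flag outside
the Venn. Genes missing one of the two sequences are excluded from the
categories needing it, logged. Dubious-ORF exclusion is an input list,
not hardcoded.

## Translatability scores

TE is footprint reads / mRNA reads; zero-mRNA genes are flagged NaN, never
silently 0. CSC is the per-codon Pearson correlation, across genes,
between codon frequency and mRNA half-life; zero-variance codons are
flagged undefined. CSCg is the plain occurrence-weighted mean of CSC over
a gene's sense codons (stop excluded), so the CSCg of a concatenation is
the occurrence-weighted mean of the parts.

The decile-banded normalization ranks the genome into eight equal-count
groups ("equal groups" is read as equal-count octiles by rank, not
equal-width value bins), splits each extreme octile at its median (ten
groups total), min-max normalizes each group internally, and maps the
groups onto fixed bands: [0, 0.0625] for the lowest, [0.9375, 1] for the
highest, and eight equal consecutive bands over the middle. Metrics where
a low raw value means efficient initiation (initiation time, 40S 5′UTR
density) are inverted first, so 1 is always the efficient end. Ties are
assigned to groups by stable sort order and logged; a globally constant
metric returns identical scores (0.5) for all genes. Group membership is
rank-based, hence invariant to monotone transforms of the raw metric;
within-band interpolation follows the raw values.

Group comparisons use the two-sample two-sided Kolmogorov–Smirnov test
and Welch's unequal-variance t-test of each group against the rest of the
genome, with a significance mask at p ≤ 0.05. Missing values are excluded
pairwise. Clustering is agglomerative with Euclidean distance; only the distance
metric is fixed by the method, so the linkage criterion is a genuinely
open choice — average linkage is the default and is exposed as a
parameter. All-missing rows are excluded; remaining gaps are
median-imputed, flagged.

## Monosome profiles

A-site offsets: 16th nt (28 nt reads), 17th (29–31), 18th (32), first
read nt = 1; other lengths have no calibrated rule. For the short
empty-A-site class (20–23 nt) no published offset exists, so the read
midpoint is used; this package convention is flagged in the provenance
output. Reads extending past the CDS are dropped and logged. `full_read`
profiles increment every covered nucleotide (used for length-class
enrichment views); `a_site` profiles increment only the A-site position.

Windows of ±150 nt around a feature anchor are normalized by the window
sum, so each retained gene contributes a vector summing to 1 and
sequencing depth cancels. Windows clipped at a CDS edge are kept when at
least 50% of their span remains (configurable); clipped positions are NaN
and excluded from averaging. Zero-coverage windows exclude the gene,
logged. Metagenes are per-offset means; group-vs-control differences use
per-offset Welch t-tests with Holm–Šídák family-wise adjustment across
the 301 offsets. Zero-variance offsets with equal means yield p = 1.
Replicates are pooled by summing counts before normalization.

## Disome processing

Two dialects: *broad* accepts 50–80 nt reads untrimmed; *narrow* trims
2 nt from the 5′ end and 5 nt from the 3′ end, then accepts 57–63 nt.
Trimming precedes filtering — the accepted ranges are quoted post-trim,
and reversing the order would change the accepted set (a fixture asserts
this). The leading (3′) ribosome's A site is the codon containing the
46th nt of the processed read. Collision peaks are located as the argmax
of the codon-resolution metagene within ±25 codons of the anchor, ties
toward the smaller offset; the count of offsets at or above half-maximum
(baseline-subtracted) is reported as a width, separating sharp post-ICP
peaks from the broad peak ~9–10 codons downstream of polybasic
stretches. Queued-ribosome periodicity is reported only descriptively as
raw spacings between local maxima; no formal periodicity test is applied
because none is established for these data.

## Synthetic data

The generators emulate the statistical shape of the public monosome and
disome data sets the analyses were designed for, not their biology:
uniform background coverage with a multiplicative pause, not codon-level
dwell-time variation; no sequencing error, UMIs or multimapping; and a
background amino-acid composition uniform over the 20 residues (correct
composition is irrelevant to scanner correctness). Passing tests
therefore demonstrate that the machinery recovers planted signals
exactly, not that real libraries are this clean.

Planted genes are built by rejection-sampling an architecture-free
background, overwriting a motif wrapped in a 30-residue charge-free
buffer (so neighbouring background cannot tip a scanning window), and
verifying with the scanners that the gene satisfies exactly its intended
categories — generation fails loudly otherwise. Motifs: 9-in-10 K/R with
runs ≤ 5 for (a); a 6-K run for (b); three AAA-coded lysines followed by
an A-initial codon (a 10-adenine tract) for (c); twelve K spread over 24
residues for (d); a twelve-K AAA-coded run satisfies all four at once.
Planted K runs are coded AAG by default (charge without poly(A)); setting
the lysine codon to AAA turns runs of ≥ 4 K into bona fide poly(A)
tracts, and the truth table then records both flags. Back-translation
rejection-samples background codons so no stray poly(A) tract or ICP
appears.

Footprints: A-site nucleotides are sampled uniformly over the feasible
range (19..L−15, where every 28–32 nt read fits), with the 9 nt downstream
of a stall anchor upweighted by the pause factor (default 3); lengths are
uniform on 28–32 and the 5′ end is back-computed by inverting the offset
rule, so A-site estimation recovers the sampled codon exactly. An optional
short-read fraction emits 20–22 nt reads at stall positions (midpoint
placement), emulating empty-A-site accumulation. Disomes plant the
leading ribosome's A site a configurable 9 codons (default) past the
anchor in a configurable fraction of reads (default 0.5 background), with
raw lengths drawn per dialect including the to-be-trimmed ends. Metric
tables are multivariate normal with a single-factor correlation structure
(corr(TE, CSCg) = +0.5, positive Kozak loadings, negative initiation-time
and 40S-density loadings) or a user-supplied full correlation matrix,
which must be positive definite; observable scales are log-normal where
the quantity is positive (TE, initiation seconds, 40S density).

Defaults: 200 genes of 150–400 aa, 50 reads/gene, 30 disomes/gene, seed 0.
All randomness flows through one `numpy.random.Generator` derived from
the config seed; reruns are byte-identical. The pause-recovery check in
the test suite uses 200 stalled + 200 control genes of 150 aa at 100
reads/gene — the density at which a 3-fold, 9-nt pause stands clearly
above a 301-offset Holm–Šídák family — and the disome-geometry check uses
50 genes at 30 disomes/gene.

## Numerical and degenerate-input choices

- Window scans use exact integer cumulative sums; no floating-point
  windows.
- Normalized windows must sum to 1 within 1e−9; NaN marks clipped
  positions only.
- `max_net_charge` ties break to the earliest window; collision-peak ties
  break to the smaller offset.
- Empty sequences, invalid alphabet characters (with position), negative
  counts, anchors outside the CDS, unknown length classes and empty
  groups all raise immediately with named errors; recoverable oddities
  (partial codons, reads past the CDS, undefined TE/CSC) are logged and
  flagged, never silently zeroed.

## Known limitations

Alignment, rRNA depletion and multimapper resolution are upstream (SAM
ingest keeps primary, uniquely-mapped records only). Kozak scores,
initiation times, half-lives and 40S densities are consumed as published
per-gene tables, not recomputed. The trailing (5′) ribosome of a disome
is not modelled. ICP-driven frameshifting is out of scope. The decile
normalization's tie rule makes scores of tied raw values order-dependent
(logged when it triggers).
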