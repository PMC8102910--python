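# polystall

Tools for asking whether polybasic protein segments — runs of lysine (K)
and arginine (R) that must thread through the negatively charged ribosome
exit tunnel — behave like translation-stalling sequences in budding yeast.
The package is aimed at people analysing ribosome-profiling data against
CDS-level sequence features: it scans a proteome for polybasic
architectures, scores how well the flagged genes are translated, and
measures monosome and disome (collided-ribosome) footprint density around
the suspect sequences.

## What it computes

**Architecture scan** (`polystall.seqscan`). Four arrangements of
polybasic sequence are detected, plus inhibitory codon pairs (ICPs) as an
endogenous stalling control:

- (a) ≥ 8 K/R within a 10-residue window;
- (b) ≥ 6 consecutive K/R;
- (c) ≥ 10 consecutive adenines in the CDS (a poly(A) tract, which can
  cause ribosome sliding independently of the encoded lysines);
- (d) net charge ≥ +12 in a 30-residue window, the approximate length of
  nascent chain held in the exit tunnel. Charge counts K,R as +1 and D,E
  as −1; terminal charges are ignored.
- in-frame inhibitory codon pairs (e.g. CGA-CGA), supplied as a list.

Per-gene flags, Venn region counts and hit positions (relative to gene
length) are reported.

**Translatability scores** (`polystall.translatability`). The codon
stabilization coefficient (CSC: per-codon Pearson r between codon
frequency and mRNA half-life) and its gene mean CSCg; translation
efficiency TE = footprint reads / mRNA reads; a decile-banded 0–1
normalization for initiation metrics (octiles with split extremes, each
group min-max normalized into its genome-wide band, so a handful of
extreme genes cannot compress the scale); Kolmogorov–Smirnov and Welch
t comparisons of gene groups against the rest of the genome; Euclidean
hierarchical clustering of the score matrix.

**Ribosome profiling** (`polystall.riboprof`, `polystall.disome`). The
A site of a 28–32 nt monosome footprint is the codon containing the
16th/17th/18th nt of the read (for 28 / 29–31 / 32 nt reads, first nt = 1).
Coverage around a feature anchor is normalized per gene by the summed
reads in a ±150 nt window, averaged into metagene profiles, and tested
per offset (Welch t with Holm–Šídák adjustment). Disome reads are
processed under two dialects (accept 50–80 nt untrimmed, or trim 2 nt/5 nt
from the ends then accept 57–63 nt); the leading ribosome's A site is the
codon containing the 46th nt, and collision peaks are located as the
metagene argmax in codons relative to the anchor.

**Synthetic data** (`polystall.synthdata`). Seeded generators plant each
architecture into background proteins that provably carry none, simulate
footprints with configurable pause sites (and disomes with a planted
leading-ribosome offset), and emit metric tables with a chosen
correlation structure — so the whole pipeline is testable offline.

## Worked example

```sh
polystall run --seed 42 --out-dir demo
```

simulates a 200-gene proteome (3 genes planted per architecture and 3 ICP
genes), scans it, scores a 2000-gene synthetic metric table, builds the
monosome metagene around the planted anchors and locates disome collision
peaks under both dialects. It prints

```
pipeline complete; report bundle in demo
```

and `demo/` then holds `flags.tsv`, `venn.tsv`, `hits.tsv`,
`normalized_scores.tsv`, `metagene.tsv`, `disome_peaks.tsv`, the planted
truth table, and a `provenance.json` recording seed, thresholds and input
digests. In `demo/venn.tsv` the singleton regions hold exactly the
planted counts (`a 3`, `b 3`, …); `demo/disome_peaks.tsv` reads

```
dialect  n_genes  peak_offset_codons  peak_width
  broad       15                   9           1
 narrow       15                   9           1
```

i.e. the collision peak sits 9 codons downstream of the polybasic anchor
— exactly where the generator planted the leading ribosome — under both
processing dialects.

Individual stages are available as `polystall scan`, `scores`,
`metagene`, `disome` and `simulate`; see `polystall <cmd> --help`.

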