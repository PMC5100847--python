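# Methods

This note documents the models behind `hapspec`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical choices that matter when reading results.

## The k-mer spectrum model

For a diploid genome of haploid length G sequenced to depth c per
haplotype, the multiplicity histogram n(m) of canonical k-mers decomposes
into three components:

1. **error spike** near m = 1 — each sequencing error creates a word that
   almost never recurs;
2. **haploid peak** at c₁ ≈ c·(L−k+1)/L for read length L — words present
   in only one haplotype because a heterozygous site falls inside their
   window;
3. **diploid peak** at c₂ ≈ 2c₁ — words shared by both haplotypes, plus
   repeat words at higher multiples.

`fit_spectrum` locates these landmarks and partitions the k-mer mass
(instances, Σ m·n(m)) into error mass (m ≤ e*), haploid-peak mass M₁
(e* < m ≤ valley) and everything else M₂. The partition is exact:
error + M₁ + M₂ equals the histogram's total mass.

### Genome size

The classic summation divides the haploid-peak mass by the haploid depth,
all other mass by the diploid depth, and sums:

    G_sum = M₁/c₁ + M₂/c₂.

M₁/c₁ estimates the number of *distinct haplotype-private words* — and an
isolated het site contributes k private words on **each** haplotype, so
M₁/c₁ counts every heterozygous locus roughly twice while M₂/c₂ counts
every homozygous locus once. G_sum therefore measures the distinct k-mer
content of the diploid, which exceeds the haploid length by a factor of
about 2 − e^(−kH) (≈ 1.23 at H = 1.25%, k = 21). The haploid-consistent
estimator halves the haploid-peak component:

    G = (M₁/c₁)/2 + M₂/c₂,

and this is the quantity that recovers the simulated haploid length
(within ~2% at 30× error-free coverage; within ~10% with 0.5% read
error). `GenomeSizeEstimate` reports both, labelled; heterozygosity and
all parameter-recovery checks use the haploid-consistent G. In the
homozygous limit (M₁ = 0) both reduce to M₂/c₂, which equals total
non-error mass over c₂ and is exact up to peak-location error: every
haploid position contributes 2c₁ = c₂ of mass whether shared or not,
which is also why M₂ needs no repeat correction — a two-copy repeat
carries twice the mass and is counted twice, as it should be.

### Heterozygosity

    H = (M₁/c₁) / (2·k·G)

is a first-order model: each het site creates 2k haplotype-private
distinct words, provided no other het site falls within the same window.
Clustered SNPs share windows, so the realised private-word count is
2G·(1 − e^(−kH)) rather than 2GkH and the estimator is biased low by
roughly kH/2 (−10% at H = 1.25%, −18% at H = 2%, with k = 21). This is
accepted and documented rather than corrected: the estimator is meant as
a transparent first-order readout, not a mixture-model fit (full spectrum
mixture modelling with explicit error and repeat components is
deliberately out of scope).

### Numerical choices in the fit

- **Error cutoff e\***: located on the *raw* histogram as the earliest
  minimum before the first rise. Smoothing first would smear the m = 1
  spike into neighbouring bins and fabricate peaks at low depth. There is
  no universally agreed definition of "error k-mers" from a histogram
  alone; mass at m ≤ e* is this package's operationalisation.
- **Peak detection**: bins at or below e* are zeroed, the rest smoothed
  with a centred moving average (default window 5, reflected ends), and
  interior local maxima collected; maxima below 5% of the tallest peak's
  height are discarded as noise. The tallest peak is then paired with a
  companion in (1.5×, 3×] its depth (companion is the diploid peak) or in
  [⅓×, ⅔×) (companion is the haploid peak). A spectrum with one
  significant peak is treated as homozygous: c₁ absent, M₁ = 0. If two or
  more significant peaks exist but none is in a companion band, c₂ falls
  back to 2c₁.
- **Valley**: the smoothed minimum strictly between c₁ and c₂; it is the
  M₁/M₂ boundary. Whether a fixed or fitted boundary is preferable is
  genuinely open; the fitted valley adapts to depth and was chosen for
  that reason.
- Multiplicities are capped at 10,000; mass above the cap accumulates in
  the cap bin (the k-mer-counter `histo` convention). Canonical counting
  (lexicographic min of word and reverse complement) is the default; k is
  21 by default for desk-scale work and any odd k ≤ 31 is accepted.

## Redundancy removal

Overlaps are found natively: shared-k-mer seeds (both strands, seed
k = 21), grouped by diagonal, the best diagonal chained and scored by
exact column comparison with X-drop extension (drop 30 at +1/−1 scoring).
The aligner is deliberately **gap-free**: the divergence it targets is
substitution-style haplotype divergence, and gap-free scoring makes the
20%-of-smaller-contig overlap fraction unambiguous. Containment is tested
first (if the whole smaller sequence fits on the diagonal and its
full-length identity clears the threshold, `frac_small` is exactly 1),
which keeps the containment predicate stable for the cleaning pass.

**Collapse** removes, per round, the smaller contig of every pair with
`frac_small` ≥ 0.20 (inclusive) and identity ≥ 0.95; rounds repeat until
nothing is removed (max 50). Decisions within a round are taken against
the round-start contig set, so output is order-independent; equal-length
ties remove the lexicographically later id, for determinism. Contigs at
or below 600 bp never participate but are retained and flagged — the
conservative choice. The identity floor of 0.95 tolerates ~1.25%
haplotype divergence plus alignment noise and is exposed as a flag.

**Cleaning** is a single pass removing scaffolds shorter than 50 kb
(strict) that are contained in a strictly longer scaffold at ≥ 99%
identity — stricter than collapse because its targets are same-haplotype
assembly artifacts.

On desk-size fixtures (≤ 30 contigs of ≤ 2 kb) the removal decisions are
verified identical to a brute-force Smith–Waterman oracle
(`Bio.Align.PairwiseAligner`, local mode); the oracle lives in the test
suite and never substitutes for the implementation.

## Coverage classification

`pseudo_map` assigns each read to the contig sharing the most canonical
seed k-mers (minimum 3 votes; ties discarded as ambiguous; read span
inferred from the seed diagonals and clipped to the contig). It ignores
pairing and gapped alignment — classification consumes only *mean depth
ratios*, for which vote-based placement is sufficient, as the ≥ 90%
label-accuracy recovery on truth-labelled assemblies shows. Identical
multi-copy sequence is the known failure mode: reads from exact duplicate
copies tie and are discarded, so duplicate-aware simulations for mapping
tests use divergence or single copies.

Classification uses a threshold of 0.75× the expected depth d — the
midpoint of the 0.5× (haplotig) and 1× (collapsed) modes — with
strict-below semantics; an optional refinement moves the threshold to the
empirical valley between the modes when both are detectable. d can be
supplied (it is, in the recovery tests, as 2× the simulated per-haplotype
depth) or estimated as the median mean-depth of contigs ≥ 5 kb. Genome
size from coverage is ½·Σlen(haplotig) + Σlen(collapsed). Two-copy genes
are called `SPLIT_HAPLOTYPE` below 0.75d and `TRUE_DUPLICATE` otherwise,
with the summary reporting the 1×-class fraction.

## Summary statistics

- N50 takes an external genome size G (NG50 semantics): sort lengths
  descending and report the length at which the running sum first reaches
  G/2, returning 0 with a warning when the assembly is smaller than G/2.
- Mean scaffold size truncates rather than rounds — verified against the
  published draft-report cells it reproduces (1,182,727,890/94,394 →
  12,529, which rounding would print as 12,530).
- Percentages round half-up to two decimals (10.4446 → 10.44), matching
  repeat-mask report conventions; `decimal` arithmetic avoids binary
  round-to-even surprises.
- Mask summaries union intervals within a class (and across classes for
  the TOTAL row), never double-counting overlaps.

## The synthetic data generator

`simulate_diploid` draws an i.i.d. base sequence at the configured GC
(default 0.35, a typical broadleaf-tree value), optionally appends
segmental-duplication copies (identical in both haplotypes), and creates
haplotype B by i.i.d. substitutions at per-site rate H (default 0.0125,
the heterozygosity scale of a highly outcrossing tree). Reads are uniform
single-end draws per haplotype (default 150 bp, 30× per haplotype,
error-free; substitution errors i.i.d. when enabled). The draft assembly
fragments the genome into exponential pieces (mean 8 kb, 200-bp floor,
breaks forced at duplication boundaries); heterozygous fragments split
into two haplotigs with probability `split_probability` (default 0.5).
All outputs are byte-reproducible from the config seeds.

What it does **not** emulate — and hence what passing tests do not show
about real data: indel variation and structural variants, non-uniform
(GC-biased, platform-specific) coverage and error profiles, paired-end
geometry, real repeat landscapes beyond simple segmental duplication, and
assembler-specific artifact structure. The generator validates the
*estimators' logic* under their stated assumptions, not their robustness
to everything a real sequencing run produces.

## Problem sizes

Recovery tests run on 200–500 kb genomes at 30× per haplotype (order
10⁷ k-mers), which puts peak depths near 26/52 — deep enough for the
Poisson peak widths (≈ ±5/±7) to separate cleanly, exactly as the
50×/100× peaks separate in real deep short-read data — while keeping the
whole suite in minutes. Vectorised 2-bit counting makes the k-mer stage
linear and memory-light (packed uint64 words, k ≤ 31).

## Known limitations

- The gap-free aligner understates overlap for indel-divergent sequences;
  it is not a general-purpose aligner.
- The heterozygosity readout is first-order and biased low at high kH
  (quantified above).
- `pseudo_map` discards ties, so exactly-identical duplicated contigs
  receive no unique reads (see above).
- Peak pairing assumes at most two coverage modes besides errors and
  repeats; polyploid spectra are out of scope.
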