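# Methods

## Scope and model

`wgdkit` implements the comparative-genomics core of a paleopolyploidy
analysis: given gene orders and protein homology hits for one or two
genomes, it (i) chains homologous gene pairs into collinear blocks, (ii)
estimates synonymous distances (Ks) between coding sequences, (iii) fits
Gaussian mixture components to block-median Ks and converts peak positions
into event ages by proportional calibration, (iv) quantifies post-polyploidy
gene loss against a reference genome with a geometric run-length model, and
(v) replays and interrogates chromosome-level rearrangement histories
through a telomere-centric karyotype engine. A synthetic genome-evolution
generator with complete ground truth underwrites all tests.

## Collinear blocks

Homologous gene pairs are placed in (order-index A, order-index B) space per
chromosome pair. A block is a chain of pairs with strictly monotone indices
on both axes (ascending/ascending for orientation +1, ascending/descending
for −1) and consecutive gaps of at most `max_gap` skipped genes (default
25) on either axis. Chains are found by longest-chain dynamic programming —
the chain score is simply the number of pairs, with no gap penalty, which
keeps the optimum exactly checkable by exhaustive search — and extracted
greedily by descending pair count; each pair belongs to at most one block
and chains below `min_pairs` (default 5) are discarded. Ties between
equal-score chains are broken by the smallest starting A-index. Axes are
order indices, not base pairs, so `max_gap` reads directly as "skipped
genes", the same units as the fractionation statistics.

## NG86 synonymous distance

Synonymous/nonsynonymous sites are counted per codon as the fraction of
one-step nucleotide changes that preserve the amino acid (universal code),
averaged over the two sequences; changes into stop codons count as
nonsynonymous sites excluded. Codons differing at d positions average their
synonymous/nonsynonymous step counts over all d! minimal substitution paths
with equal weight, excluding paths that pass through a stop; if every path
is blocked, the codon pair is skipped (and contributes no sites, preserving
S + N = 3 × compared codons exactly). The same pairwise-skip rule applies
to codons containing gaps or ambiguity characters. Proportions ps = Sd/S
and pn = Nd/N are corrected with the Jukes–Cantor transform
d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is reported as saturated rather than
raising. Site counts are kept at full precision; no rounding precedes the
correction. Ks values above 5.0 are treated as saturation-adjacent and
excluded from peak fitting.

## Peak fitting, rate correction, dating

Mixtures are fitted on block medians, not raw pair Ks — medians sharpen
event peaks considerably. Fitting uses expectation–maximization
(scikit-learn's `GaussianMixture`) with k-means initialization, best of 10
restarts by likelihood, deterministic for a given seed; a variance floor of
(1e-4)² prevents component collapse and fitted σ values are floored at
1e-4. The component count k is user-specified (three components describe a
genome carrying two duplications on top of the ancient hexaploidy signal);
a BIC scan is available but not the default. Rate correction aligns a
shared-event peak across datasets by multiplying every component mean and
sd by reference_mu / shared_mu, leaving weights and mean ratios invariant.
Event ages follow by linear proportional dating,
t = (ks_event / ks_calib) · t_calib, against the core-eudicot hexaploidy
interval 115–130 Mya; with peak medians 0.30 and 1.90 this yields
18.2–20.5 Mya for the younger duplication. Blocks are assigned to events by
maximum posterior responsibility of their median under the fitted mixture,
with a 0.6 threshold below which a block stays unassigned — this avoids
coin-flip labels between overlapping components.

## Fractionation

A reference gene is retained in a query subgenome iff it participates in a
block pair assigned to that subgenome; genes outside any block footprint
are excluded from the denominator. Loss runs are maximal stretches of
absent reference genes bounded by retained genes within one contiguous
footprint segment; runs touching a footprint edge are unbounded and not
counted. Runs longer than `segmental_cutoff` (default 30 genes) are treated
as segmental losses and excluded from the run-length table. The geometric
model N_k = N₁·p^(k−1) is fitted two ways: a log-linear regression of
ln N_k on (k−1) restricted to lengths with N_k ≥ 5 (avoiding
log-of-small-count instability), and the assumption-free closed-form MLE
p̂ = Σ(kᵢ−1)/Σkᵢ over all runs; both are reported so either convention can
be compared. Goodness of fit is an extra-parameter F test of the geometric
decay against the two-parameter alternative N_k = N₁·p^(k−1)·k^b (H0:
b = 0): a large tail probability means the geometric law is adequate. This
construction was chosen over an overall-regression-significance F, which
would behave in the opposite direction. Exactly geometric counts give
p-value 1 by convention (zero residual), and a perfectly k^b-shaped table
gives p-value 0.

## Karyotype engine

Chromosomes are ordered lists of oriented segments labelled by ancestral
chromosome, spans being fractions of the ancestral unit interval. EEJ
concatenates two chromosomes (default end-of-first to start-of-second) and
NCF inserts a donor at a host breakpoint (default 0.5, a centromere proxy);
each reduces the chromosome count by one and records one satellite remnant
from the joined telomeres. Satellites never re-enter the karyotype and are
excluded from counts, consistent with their loss during evolution. XO is a
strict two-chromosome reciprocal translocation of distal arms; IV reverses
segment order and orientations within an interval; WGD/WGT copy every
chromosome with a/b(/c) suffixes. Breakpoints at exactly 0 or 1 are
rejected as degenerate. Event scripts are plain text, one event per line.

Fusion timing relative to a duplication is inferred from adjacency copy
number: a junction of two distinct ancestral chromosomes present in two or
more duplicated copies predates the duplication; present in exactly one
copy, it most likely postdates it. Singleton junctions whose flanking
ancestral ends participate in a different junction elsewhere are reported
as `ambiguous` — the sister junction may have been disrupted by a later
crossover — rather than being forced into either class. Junctions already
present in the supplied ancestor are skipped.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes: a
shared ancestral gene order; lineage divergence at a configured synonymous
distance; per-lineage scripts of WGD/WGT/EEJ/NCF/XO/IV events, each stamped
with a Ks age (the simulation clock — calendar time enters only through an
explicit calibration downstream); geometric segment-wise gene loss after
each duplication (initiation probability per retained gene, default 0.2;
continuation probability default 0.28, the value estimated from real
fractionation data); and homology hits whose bitscores decay exponentially
with true Ks so the closest relative is always the best hit. Loss runs
never delete the last surviving copy of a gene, so fractionation removes
duplicates only. Recorded run lengths are the generated geometric draws
(truncated only at chromosome ends or protected copies); in the genome,
overlapping runs merge, so realized deletion stretches are longer than the
generating law — a property real fractionation data shares.

In table mode, observed pair Ks is true Ks plus Gaussian noise (default sd
0.05) truncated at zero. In sequence mode, codon sequences accrue
Poisson-distributed synonymous substitutions along the copy tree with
branch lengths set so that each pair's expected pairwise divergence equals
its true Ks. The codon alphabet is restricted to the 24 codons of
Val/Ser/Pro/Thr/Ala/Gly: every codon then carries exactly one synonymous
site (the fourfold-degenerate third position) and no synonymous one-step
change elsewhere, so the synonymous process is exactly four-state
Jukes–Cantor and the NG86+JC estimator is unbiased for the planted
distance. An optional fixed Ka/Ks scalar adds nonsynonymous changes
(default 0, i.e. purely synonymous divergence).

What the generator does **not** emulate: indels and alignment error,
codon-usage and rate heterogeneity across genes and sites, tandem-array
birth–death dynamics (beyond optional fixed-size arrays for classifier
testing), transposon-mediated gene movement, biased subgenome dominance,
and assembly artefacts. Green tests therefore demonstrate correctness of
the algorithms under the stated generative model, not robustness to every
property of real genome data.

## Problem sizes and determinism

Default simulated study conditions are five chromosomes of 500 genes (the
orthologous-ratio analyses) and three-to-four chromosomes of 250–300 genes
for the end-to-end Ks-peak recovery, which give hundreds of blocks and
thousands of homologous pairs while keeping any single analysis in the
seconds range. All stochastic paths flow through one seeded
`numpy.random.Generator`; identical configuration and seed reproduce
byte-identical outputs, and the mixture fit is deterministic given its
seed.

## Known limitations

Proportional dating inherits the constant-rate assumption of its
calibration; the rate-correction step aligns shared-event peaks linearly
and does not model lineage-specific rate variation beyond that single
factor. The greedy chain extraction guarantees optimality of the first
chain per chromosome pair, not of the full partition. The duplicate-type
classifier is an intentionally simplified priority scheme. The fusion-
timing rule assumes junction coordinates survive exactly; rearrangements
that erode a junction's flanks will push it to `ambiguous`.
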