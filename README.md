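# wgdkit

Comparative-genomics toolkit for detecting, dating and dissecting ancient
whole-genome duplications (WGDs) from gene order and coding-sequence
divergence — written for genome-paper-style analyses of paleopolyploid
plant genomes, and for anyone who wants those analyses reproducible and
testable on synthetic genomes with known ground truth.

## What it does

* **Collinear blocks** — dynamic-programming chaining of homologous gene
  pairs in order-index space (strict monotonicity, gap cap, both
  orientations), the unit of every downstream statistic.
* **Ks estimation** — Nei–Gojobori (NG86) synonymous/nonsynonymous
  distances with Jukes–Cantor correction,
  d = −(3/4)·ln(1 − (4/3)p), including exact multi-path averaging for
  codons differing at several positions.
* **WGD detection and dating** — Gaussian-mixture (EM) fitting of
  block-median Ks distributions; each duplication leaves a peak μ±σ.
  Shared-event peaks are aligned across datasets (rate correction), and
  ages follow by proportional calibration, t = (Ks_event/Ks_calib)·T_calib,
  against the core-eudicot hexaploidy (γ, ~115–130 Mya).
* **Orthologous ratios** — modal counts of matched syntenic regions per
  genomic window (a 2-WGD lineage shows a 1:4 ratio against an unduplicated
  sister, 4:2 against a 1-WGD relative).
* **Fractionation** — gene-retention profiles against a reference genome
  and the geometric run-length model of consecutive gene loss,
  N_k = N₁·p^(k−1), with both a log-linear and a closed-form MLE estimate
  of the extension parameter p and an extra-parameter F test of fit.
* **Karyotype event calculus** — a telomere-centric engine for end-to-end
  joining (EEJ), nested chromosome fusion (NCF), arm crossovers (XO),
  inversions and whole-genome duplications/triplications, with satellite
  bookkeeping, predicted dot-plot tracts, and inference of fusion timing
  relative to a WGD from duplicated adjacencies.
* **Synthetic genomes** — a generator that plays lineage scripts of the
  events above over a shared ancestral gene order, with geometric
  post-duplication gene loss and Ks-faithful hits/sequences, emitting full
  ground truth for validation.

## Worked example

Simulate a genome that carries an old triplication signal (Ks 1.90) plus
two nested WGDs (Ks 0.66 and 0.30) with geometric gene loss, run the
intra-genome pipeline, and date the duplications:

```python
import wgdkit as w
from wgdkit.simdata import SimConfig, simulate

cfg = SimConfig(
    n_chromosomes=4, genes_per_chromosome=250,
    lineage_scripts={"P": [("WGT", 1.90), ("WGD", 0.66), ("WGD", 0.30)]},
    divergence_ks=1.90, loss_extension_p=0.3, loss_initiation_rate=0.2,
    ks_noise_sd=0.05, seed=202,
)
res = simulate(cfg)
blocks = w.detect_blocks(res.hits[("P", "P")], res.tables["P"], res.tables["P"])
for b in blocks:
    w.block_median_ks(b, res.observed_ks)
medians = [b.median_ks for b in blocks if b.median_ks and 0 < b.median_ks <= 5]
print(f"{len(blocks)} collinear blocks, {len(medians)} with a median Ks")

peaks = w.fit_ks_peaks(medians, k=3, seed=0)
for c in peaks.components:
    print(f"peak mu={c.mu:.3f} sigma={c.sigma:.3f} weight={c.weight:.2f}")

d = w.date_event(peaks.means[0], peaks.means[2], (115.0, 130.0))
print(f"younger WGD: {d.t_low:.1f}-{d.t_high:.1f} Mya")
d = w.date_event(peaks.means[1], peaks.means[2], (115.0, 130.0))
print(f"older WGD:   {d.t_low:.1f}-{d.t_high:.1f} Mya")
```

which prints:

```
264 collinear blocks, 264 with a median Ks
peak mu=0.299 sigma=0.008 weight=0.09
peak mu=0.660 sigma=0.007 weight=0.18
peak mu=1.901 sigma=0.009 weight=0.73
younger WGD: 18.1-20.4 Mya
older WGD:   40.0-45.2 Mya
```

The mixture recovers the three planted peaks; taking the oldest peak as the
calibrated hexaploidy, proportional dating places the younger duplication
at ~18–20 Mya and the older at ~40–45 Mya. The same steps are available
from the shell via the `wgdkit` CLI (`simulate`, `rankhits`, `blocks`,
`ks`, `peaks`, `date`, `fraction`, `karyo-apply`, `karyo-infer`,
`classify-dups`); every subcommand logs its parameters, seed and input
hashes to stderr.

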