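# Methods

This note documents the models, parameter choices and numerical decisions
behind `prc2sig`, and what the synthetic benchmark does and does not show
about real data.

## The synthetic benchmark

`prc2sig.syndata` emulates a PRC2-inhibitor experiment in a sensitive tumor
line at desk scale. Five promoter archetypes are generated at fixed
proportions (baseline 30%, methylated 20%, quiescent 15%, active 20%,
PRC2-target 15%) with the mean promoter profiles

| archetype   | H3K27me3 | H3K4me3 | ATAC | methylation β | expected log2FC |
|-------------|---------:|--------:|-----:|--------------:|----------------:|
| baseline    | 1.0      | 5.0     | 5.0  | 0.25          | 0               |
| methylated  | 0.8      | 1.0     | 1.0  | 0.85          | 0               |
| quiescent   | 1.5      | 0.3     | 0.3  | 0.05          | 0               |
| active      | 0.3      | 10.0    | 10.0 | 0.10          | 0               |
| prc2_target | 8.0      | 3.0     | 2.0  | 0.15          | `effect_log2fc` |

Signal units are arbitrary depth-normalized track units. The PRC2-target
archetype is bivalent by construction — the dominant H3K27me3 promoter
signal with moderate H3K4me3 — and is the only archetype with a treatment
effect (default +2 log2 units), reflecting de-repression after loss of the
repressive mark. The separations were chosen once so that the five-type
structure is recoverable by the clustering stage, which is the purpose of
the benchmark; the per-gene noise is multiplicative lognormal on track
levels (σ = 0.25), additive Gaussian on methylation β (σ = 0.06), and
negative-binomial sampling noise on counts (dispersion 0.05, mean 200,
triplicate arms, matching a typical well-powered RNA-seq design).

Geometry: genes are 2 kb bodies on a 50 bp grid with ≥ 6.2 kb gaps, so every
TSS ± 3 kb promoter window is disjoint from its neighbors' and aligns with
painted bins; with zero signal noise the promoter mean therefore equals the
archetype mean exactly, which pins down the quantification conventions in
tests. Each generator draws from a named substream of the configured seed
(`SeedSequence([seed, crc32(name)])`), so outputs are reproducible
independently of call order.

The cohort generator produces log2(RPM)-scale expression for a configurable
number of samples (default 500, close to the 498-sample neuroblastoma cohort
that motivates the stage). A latent standard-normal factor drives the marker
gene (`EZH2`); PRC2-target genes load on `ρ·z + √(1−ρ²)·u` with a second
latent factor `u`, giving marker↔target-mean correlation ρ (default −0.8)
in expectation, plus N(0, 0.5²) per-gene noise.

What the generator does **not** emulate: broad H3K27me3 domains and
peak-shaped signal (promoters are painted flat), read-level artifacts (GC,
mappability, duplicates), gene-length and isoform structure in counts,
batch effects, copy-number variation, and the heavy-tailed outliers of real
cohorts. Passing tests therefore demonstrate that the statistical machinery
recovers the designed structure under NB/lognormal noise — not that the
pipeline is robust to every artifact of real sequencing data.

## Spike-in normalization

`SF_i = min_j(UMD_j)/UMD_i` and `NH_i = SF_i·OH_i`. The sample with the
smallest spike-in library anchors the scale (its SF is 1), and
`UMD_i·SF_i` is constant across samples, which is the conservation property
tested. Zero spike-in counts make scaling undefined and raise an error.

## Promoter quantification

The TSS of a plus-strand gene is its start; of a minus-strand gene its last
base (`end − 1`, 0-based half-open throughout). The per-gene statistic is
the **length-weighted mean** over TSS ± `window_bp` (default 3000, matching
the −3 kb..+3 kb composite-profile range; the window is configurable and
recorded in output metadata because the exact per-gene window used upstream
of published heatmaps is generally tool-dependent). A mean rather than a sum
keeps values comparable across samples after spike-in scaling. Uncovered
bases count as zero; windows are clipped at position 0; genes on
chromosomes absent from a track get signal 0 with a logged warning.
Metagene profiles sample `n_bins` equal bins over TSS ± flank and flip
minus-strand genes so profiles run 5′→3′. Promoter methylation is the pooled
β = Σmeth/Σtotal over window CpGs; CpG-free genes yield NaN and are listed.

## Differential expression

The test is a deliberately small, self-contained stand-in for a full NB GLM
package, sufficient for threshold-based DEG calling at desk scale:

- **Normalization** — median-of-ratios size factors over genes with
  all-positive counts.
- **Dispersion** — per-gene method of moments
  (`α = (var − μ)/μ²`, within-condition variances averaged), then pooled by
  the *mean* within ~n/20 equal-occupancy bins of log mean. The bin mean is
  used rather than the median because the few-replicate variance estimate is
  right-skewed: its mean is unbiased while its median is not, and a
  downward-biased dispersion inflates the Wald statistic's tail.
- **Test** — `log2FC = log2((μ̂_t + pc)/(μ̂_c + pc))` with pseudocount 1
  normalized count (stability at zeros), delta-method SE, two-sided normal
  p, BH adjustment, and inclusive DEG thresholds log2FC ≥ 1 (≤ −1) with
  adjusted p ≤ 0.05.

Calibration on 2000-gene NB nulls with triplicates: type-I error at
p < 0.05 sits in [0.03, 0.07] and the p distribution is near-uniform
(KS < 0.05). One caveat is inherited from median-of-ratios normalization
itself: strongly one-sided differential expression (many genes changing in
the same direction) biases size factors and hence null log2FCs slightly;
FDR-calibration simulations therefore spike effects in both directions,
the standard design for checking BH control. An independent cross-check
against a DESeq2-style reference fit (pydeseq2) on a small matrix shows
log2FC agreement r > 0.95; the reference implementation is used only as a
test oracle, never inside the package.

FPKM (`count·10⁹/(length·library)`) and the qPCR `2^−ΔΔCt` fold change are
provided as small utilities with the conventional formulas.

## Typing and model selection

Clustering uses four features — expression log2FC, methylation β, H3K4me3
and ATAC promoter signal — z-scored to mean 0 and **population** SD 1
(zero-variance columns map to zeros rather than erroring). H3K27me3 is
excluded from clustering and used only afterwards to label the PRC2-target
type; permuting it can change labels but never assignments, which is tested.

k-means is Lloyd's algorithm with k-means++ initialization, 10 restarts and
tolerance 1e-6 (scikit-learn's implementation behind the module surface).
The number of clusters is chosen by the **mean silhouette coefficient** over
k = 2..10, argmax with ties to the smaller k. A turning-point ("elbow") rule
on a silhouette curve is ill-defined when the curve is not monotone, so the
argmax is used and the full per-k table is always emitted so a user can
override k. Singleton clusters contribute silhouette 0.

Genes missing any feature are dropped before clustering and enumerated in
the run report. The PRC2-target cluster is the one with maximal mean
held-out H3K27me3 (ties → lower index, logged); remaining clusters are named
for their strongest mean z-scored feature, or `quiescent` when all feature
means are negative. The signature is the sorted intersection of the
PRC2-target type with the up-DEG list, reported with Venn counts.

## Gene-set statistics

- **Fisher exact** (one-sided, greater): hypergeometric upper tail of the
  overlap at fixed margins via `scipy.stats.fisher_exact`; OR = ad/bc with
  ∞ when bc = 0. Sets are intersected with the universe first; the BH
  correction runs across sets.
- **Preranked GSEA** (minimal reimplementation, since the desktop tool's
  exact variant is unspecified): descending-score ranking with ties broken
  by gene id; hits add `|s|^w` normalized by the hit total, misses subtract
  `1/(N−|S|)`; ES is the signed maximal deviation. The null permutes gene
  labels; `p = (1 + #{|ES*| ≥ |ES|})/(n_perm + 1)` (the +1 avoids zero
  p-values) and NES divides ES by the mean |ES*| of the same sign.
- **Kruskal–Wallis** with midrank tie correction via `scipy.stats.kruskal`;
  the all-tied degenerate input returns H = 0, p = 1 by decision instead of
  erroring.

## Cohort validation

The quartile split is tie-inclusive: low = samples with marker value ≤ the
25th-percentile value, high = ≥ the 75th-percentile value, so group sizes
may exceed n/4 under ties (the published 126/125-of-498 split is likewise
not exactly n/4); sizes and bounds are always reported. An all-equal marker
has no defined split and errors. Fold change recovers the linear scale as
`2^(log2 RPM)`, averages within groups, and uses
`log2((mean_low + pc)/(mean_high + pc))` with pseudocount 1 RPM — the exact
published formula lives in supplementary material that is not restated here,
so the conventional pseudocounted mean ratio is adopted and configurable.
Up-calls use fc ≥ threshold (inclusive), optionally gated by a per-gene
Wilcoxon rank-sum test with BH. The per-type comparison reports fold-change
quartiles per gene type and a Kruskal–Wallis p across types.

## Pipeline

`run_pipeline` executes simulate → quantify → deg → cluster → enrich →
cohort. Each stage receives a named seed derived from the top-level seed
(recorded in the report); a failing stage is marked failed and its
dependents are skipped. When no GMT file is supplied, the enrichment stage
tests the signature against the ground-truth archetype gene lists — the
natural positive control on the benchmark. All artifacts are plain text;
`manifest.json` lists a SHA-256 checksum for every other file in the output
directory, and reports contain no timestamps so identical configs produce
byte-identical output trees.

## Problem sizes

Defaults were chosen so the full benchmark (2000 genes, ~22 Mb of synthetic
genome, triplicate arms, 500 cohort samples) runs end to end in seconds on
one core, the full test suite in well under a minute, and the acceptance
script in under a minute — while keeping ≥ 300 genes per archetype for
stable Monte-Carlo checks.

## Known limitations

- The NB test has no empirical-Bayes dispersion shrinkage or independent
  filtering; it is a threshold-calling stand-in, not a DESeq2 clone.
- GSEA implements a single-set preranked mode without leading-edge analysis.
- The silhouette-argmax rule can disagree with a human-judged elbow on real
  data with nested cluster structure; the emitted per-k table is the
  intended escape hatch.
- bedGraph tracks are the only supported signal format (no bigWig), and
  peak calling is out of scope: promoter windows are fixed, not
  peak-restricted.
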