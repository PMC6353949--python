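# Methods

## Problem and scope

A human tumor xenograft grown in a mouse yields sequencing libraries that
mix reads from two genomes: the engrafted human tumor cells and the murine
host tissue that forms the tumor microenvironment (TME).  `xenonet`
implements the analysis chain for a treated-vs-control xenograft RNA-seq
design: species-of-origin read partitioning, gene-level QC, two-group
negative-binomial differential expression, per-group weighted co-expression
networks with a normalized differential-connectivity statistic, module
detection/merging and permutation-based preservation scoring, and
hypergeometric over-representation analysis.  A synthetic dual-species
generator with planted ground truth makes every stage testable without
external data.

Upstream steps (read trimming, alignment, per-read counting by an aligner
toolchain) are a consumed contract: the package starts from per-read
dual-genome alignment summaries and gene × sample count matrices.

## Read partitioning

Each read carries mapped flags and alignment scores for the human and mouse
genomes separately.  A read mapping to only one genome is unique to that
species; a read mapping to both is discarded as ambiguous when its two
scores differ by at most a margin (default 0 — equal similarity), otherwise
it is assigned to the higher-scoring genome.  A stricter mode discards any
dual-mapped read regardless of score, covering the filter-out variant of
species-specific workflows; which of the two rules an upstream pipeline
used is often ambiguous, so both are exposed and neither is asserted as
canonical.  Species-unique reads increment their annotated gene by one;
reads without a single unambiguous gene annotation are tallied separately
(`no_feature`, `ambiguous_feature`).

## QC filter

A gene is excluded when more than ⌊n/2⌋ of its counts are zero, or when its
mean count is below 10 **and** its sample standard deviation (n−1
denominator) is below 5.  The conjunction is the literal reading of the
rule this filter reproduces; an `or` mode is available because the
published survivor counts cannot disambiguate the intended connective.
Network input is log2(count / size factor + 1).

## Differential expression

A compact NB core in the DESeq2 mould, with the simplifications stated
openly rather than bit-compatibility claimed:

* size factors: median-of-ratios over genes with no zero entry, rescaled to
  geometric mean 1;
* dispersion: per-gene method of moments on normalized counts,
  α = max(10⁻⁸, (pooled within-group variance − mean)/mean²), no shrinkage
  or trend fitting;
* test: Wald statistic on log2(mean_treated/mean_control) (0.5 pseudo-count
  when a group mean is zero) with a delta-method standard error from
  var = μ + αμ².

The Wald statistic is referred to a Student t distribution with
n₁ + n₂ − 2 degrees of freedom rather than a normal.  With five samples
per group the dispersion is estimated from the same few observations as
the means, and the normal reference is visibly anticonservative (measured
type-I rate ≈ 0.10 at nominal 0.05 on null simulations); the t reference
restores calibration (≈ 0.05).  `reference="normal"` is available.
Benjamini–Hochberg adjustment runs over tested genes only (all-zero genes
are NOT_TESTED and excluded).  Calls: UP iff adjP ≤ 0.1 and
log2FC ≥ 0.58, DOWN iff adjP ≤ 0.1 and log2FC ≤ −0.58.  The 1.5-fold
threshold is stored at full precision (log2 1.5 = 0.5849…) but calls use
the printed 0.58 so the rule matches its published form.

## Co-expression networks and K_diff

Pearson correlations are soft-thresholded into a weighted adjacency
(unsigned |r|^β by default; signed ((1+r)/2)^β available).  A gene's
connectivity k is its adjacency row sum; each group's connectivities are
divided by that group's maximum, and

    K_diff = k_norm(treated) − k_norm(control) ∈ [−1, 1].

Genes with |K_diff| > 0.6 (strict; exact ties are logged) are called
differentially connected, signed toward the group where the gene is the
better-connected hub.  β is chosen on the control network by the standard
scale-free-fit criterion (smallest β with log-log degree-distribution
R² ≥ 0.8 and negative slope, fallback 6 with a warning) and reused for the
treated network so the two scales stay comparable.  A literal
raw-correlation mode is β = 1.

## Modules and preservation

The union of the 3000 most connected genes per group (ties at the rank
boundary broken lexicographically) is clustered by average linkage on
1 − TOM, where TOM is the topological overlap matrix.  A static cut at
height 0.995 replaces the dynamic hybrid tree cut: simpler and exactly
reproducible, at the documented cost that module counts are not comparable
with dynamic-cut analyses.  Clusters below 20 genes are unassigned
("grey"); labels come from a fixed color palette by decreasing size.
Modules whose eigengenes (first PC of standardized member expression,
oriented to correlate positively with members) reach correlation ≥ 0.9 are
merged iteratively until closure.

Preservation of each control module in the treated group uses a
permutation Z composite built from two statistics: the mean within-module
adjacency in the treated network (density) and the correlation between the
module's intramodular connectivity vectors in the two networks
(connectivity).  The null re-evaluates both on random gene sets of the
same size drawn from the analyzed genes; Zsummary is the mean of the two
Z scores.  This is a two-statistic composite, not the seven-statistic
WGCNA medianRank/Zsummary battery; the interpretation bins are the
conventional ones (Zsummary > 10 highly preserved, 2–10 weak-to-moderate,
< 2 not preserved, boundaries in the middle bin).

## Over-representation analysis

For a query list of n genes in a background of N, a category of C genes
overlapping in O is scored E = nC/N, R = O/E, and rawP = exact
hypergeometric upper tail P(X ≥ O); BH adjustment runs over categories
with O ≥ 1 (the tested universe is logged since excluded categories change
m).  Poisson and binomial tails are available as cross-check modes; the
Poisson tail with mean E is the small-E limit and reproduces printed
enrichment p-values when only O and R are recoverable from a published
table (`reconstruct_ratio` backs out the implied n/N from printed rows and
flags internally inconsistent rows).

## Validation statistics

Caliper tumor volume = length × width²/2; qPCR relative expression
2^−ΔΔCt; two-sample t-tests from printed summaries (pooled df = n₁+n₂−2 by
default, Welch–Satterthwaite optional).  The published "±" spread is read
as SD by default.  Note one consequence: the day-21 tumor-volume summaries
(18.93 ± 5.39 vs 75.68 ± 25.83, n = 5/group) give t = 4.81, p = 0.0013
under the SD reading, but only p ≈ 0.06 if the spread were SEM — the SD
reading is the one consistent with the reported p < 0.01.

## Synthetic generator

Counts follow a latent-factor gamma-Poisson (NB) model: gene g in sample s
has log2 mean b + a·f_{m(g),s} + σ·ε, with one standard-normal factor per
module per sample, loading a (default 0.9), residual noise σ (default
0.4), baseline b = log2(100), and NB dispersion α (default 0.05), so the
expected latent within-module correlation is a²/(a² + σ²).  Treatment
effects add a log2FC shift in the treated group.  Rewired genes have their
factor contribution replaced by a fresh private factor in the treated
group; destroyed modules have each member's factor contribution permuted
across treated samples (decorrelates the module while preserving
marginals).  Read classes are allocated by largest-remainder rounding —
fractions are exact by construction, not sampled — with defaults
57.24 / 29.66 / 11 / 2.1 percent (the unmapped residual is an assumption;
only the first three fractions are pinned by the design being emulated).

What the generator does not emulate: batch effects, library-composition
bias, gene-length effects, mate-pair structure, or realistic dispersion
trends.  Passing tests therefore demonstrate correctness of the statistics
under the stated model, not robustness to every artefact of real libraries.

## Benchmark experiment conditions

Fixed in `xenonet.experiments` and reused by the test suite:

* **Rewiring recovery** — 2000 genes in two genome-covering modules
  (a = 0.9, σ = 0.1), 50 rewired members, 5 + 5 samples, baseline 500,
  α = 0.005 (technical-scale: at this design the biological variability is
  carried by the latent factors), unsigned β = 6.  Scored by AUROC of the
  |K_diff| ranking against the rewired flags.  With only five samples per
  group, correlation noise is the binding constraint; recovery at this
  level requires the strongly coherent modules these conditions plant, and
  degrades gracefully with weaker loadings (see the monotonicity test).
* **Preservation separation** — 500 genes, one intact and one destroyed
  60-gene module (a = 0.9, σ = 0.4), 50 samples per group, 100
  permutations.
* **DE calibration / recovery** — pure NB counts (no factors), 2000 genes,
  5 + 5, α = 0.05, baseline 100; the recovery variant plants log2FC = 2 in
  every gene and uses unit size factors (equal-depth libraries by
  construction; with all genes shifted, median-of-ratios would absorb the
  planted effect itself).

## Numerical and degenerate-input conventions

Constant genes are an error in correlation (QC is expected to remove
them); a degenerate all-zero network is an error; permutation null with
zero sd yields ±inf Z with a warning; BH caps at 1 and passes NaN through;
ties in top-gene selection, module sizes, and merge partners break
deterministically (lexicographic / larger-keeps-label).  All randomness
flows through seeded `numpy` generators; the pipeline derives per-stage
seeds as (1000·seed + stage index) mod 2³¹.

## Known limitations

No dispersion shrinkage, independent filtering, or outlier handling in the
DE core; static tree cut only; two-statistic preservation composite;
Pearson correlation only; paired-end mate conflicts out of scope.  Module
counts and DE survivor counts on real data are data-dependent and are not
a validation surface for this implementation.
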