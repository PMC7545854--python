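# Methods

This note records the statistical model behind `poolscan`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter when comparing results
with other pool-seq tools.

## Estimators

### Per-site heterozygosity and window π

For a site with base counts (n_A, n_T, n_C, n_G), combined over the pools
in scope, coverage C = Σ n_a and frequencies f_a = n_a/C,

    π̂ = C/(C−1) · (1 − Σ f_a²).

The C/(C−1) factor is the usual finite-sample correction for drawing C
reads; sites with C < 2 are undefined and skipped (logged). Window π is
the mean of π̂ over *eligible* sites: monomorphic eligible sites contribute
0 to the numerator and 1 to the denominator. Using the eligible-site count
rather than the window length as denominator avoids deflating π in windows
with patchy coverage; a window with no eligible sites is reported missing,
never zero.

This estimator deliberately does not reproduce the additional
pooled-sampling and minimum-count truncation bias corrections of
Popoolation-style tools. The brute-force per-site oracle in the test suite
defines the estimator exactly, and the correction would change all
diversity values by a roughly constant factor without affecting any of the
comparative analyses (relative diversity, F_ST, ranks).

### Watterson's θ

Per window, θ̂ = S / (a_{n−1} · L) with S the SNP count, L the
eligible-site count and a_{n−1} the harmonic number of n−1. The sample
size n is the number of chromosomes in the pool (2 × pooled individuals;
24 for pools of 12 workers, summed when pools are merged), not the read
depth: the pooled chromosomes are the sampled lineages, and read-level
resampling noise is controlled by the minimum-count filter instead. This
is a documented divergence from depth-aware pooled θ estimators, chosen
for transparency; it affects θ's absolute scale only.

### F_ST

Per SNP, the classical form

    F_ST = (π_total − π_within) / π_total,

π_within the average of the two stocks' π̂ and π_total the π̂ of their
summed counts. Sites monomorphic in the combined sample are undefined and
skipped. Negative values are retained: clamping at zero would bias
genome-wide means upward. Note one consequence of the C/(C−1) correction:
two *identical* pools with coverage C each give exactly
F_ST = −1/(2(C−1)), a small negative value rather than 0, because pooling
doubles the coverage and shrinks the correction. The genome-wide summary is
the unweighted per-SNP mean (a ratio-of-sums variant is available via
`FstTable.mean("ratio_of_sums")`).

The maximum-coverage rule — "no more than 2% of the total reads" in the
upstream filtering tradition — is implemented as a per-pool cap at the
98th percentile of that pool's coverage distribution, the standard guard
against collapsed repeats and copy-number artefacts. The wording could
also be read as a genome-wide cap or a lane-level fraction; the percentile
is configurable (`max_cov_percentile`). With fewer than 100 sites a
percentile is not meaningfully estimable and the cap is disabled with a
warning. The Q20 base-quality filter applies upstream of sync counts
(sync carries no per-base qualities) and is recorded in the config for
provenance only.

### SNP classification

A site is eligible when every in-scope pool's coverage lies in
[min_coverage, cap]; it is a SNP when additionally the combined
minor-allele count across the scope reaches min_count (combined, not
per-pool, matching the semantics of the pooled tools this format comes
from). The minor allele is the second-most-frequent base of the combined
counts. Raising min_count can only remove SNPs (property-tested).

### Stock-specific SNPs

Top-q F_ST sets (q = 1.0% and 0.1%, ties at the empirical quantile
included) are computed per pairwise comparison among the six analysis
stocks (five individual stocks plus the merged Italian background). The
published rule — "SNPs unique to that stock among these top candidates" —
is ambiguous; the default here is the strict reading: a SNP is a candidate
for stock s iff it is top-q in *every* comparison involving s, and
specific to s iff it is a candidate for exactly one stock. The looser
union reading (top-q in at least one comparison) is available via
`rule="union"`. Neither is asserted to be the published computation.

## Structure analysis

SNP columns are retained when any stock carries the site's minor allele at
frequency strictly above 0.1 (frequencies are folded to the minor allele
first). Missing pool frequencies (zero coverage) are mean-imputed per SNP
before a full-SVD PCA of the centered pool-by-SNP matrix. Clustering runs
on the leading components covering 90% of variance by default (the number
of components the original analysis used is unstated; `n_pcs` overrides).

k-means uses best-of-`restarts` (default 25) initializations per k over
k = 1..10, with

    AIC(k) = n·d·ln(W_k/(n·d)) + 2·k·d,

W_k the total within-cluster sum of squares (floored at 1e−12 so the
degenerate k = n case stays finite). k is chosen by the elbow rule:
maximize the second difference AIC(k−1) − 2·AIC(k) + AIC(k+1), ties to the
smallest k, falling back to the AIC argmin when fewer than three
consecutive k are available. Two properties of this AIC are worth knowing:
it is scale-invariant (multiplying all coordinates by a constant shifts
the curve but not its shape), and because the shared-variance likelihood
term grows faster than the 2kd penalty shrinks, its *argmin* almost never
lands at k = 1 even for perfectly homogeneous data — it is the elbow, not
the minimum, that carries the signal. On planted 3-group data the elbow
recovers k = 3 with exact membership; on homogeneous data the curve is
featureless and the tie rule returns the smallest interior k.

The published description calls this analysis both "k-nearest neighbor
(KNN)" and "iterative k-means"; it is implemented as k-means.

## Composite Selection Signal

Per contrast (each resistance-bred stock versus the merged Italian
background), F_ST values map to fractional ranks r = rank/(N+1) with
average ranks for ties — the +1 denominator keeps r strictly inside (0,1)
so the normal quantile Z = Φ⁻¹(r) is finite without clipping. Ranks are
taken within each contrast over its own SNP set *before* the per-SNP join
across contrasts. The default missing-data policy is complete cases (a SNP
must carry F_ST in all m contrasts); the "available" policy uses each
SNP's own m_i with null variance 1/m_i.

"Compared to a standard distribution" is formalized as z̄√m against the
standard normal, one-sided upper tail: the exact null for a mean of m
independent standard normals. Treating z̄ itself as standard normal would
give identical rankings (CSS is monotone in z̄ at fixed m) and hence
identical outlier sets, but mis-calibrated p-values; the √m scaling makes
the null p-values uniform, which the test suite verifies by simulation
(KS < 0.02 at 10,000 SNPs). The logistic smoothing step found in some CSS
variants is not applied. Being rank-based, CSS is invariant under any
strictly monotone transform of each contrast's F_ST values
(property-tested).

Outliers are SNPs at or above the top-0.1% empirical CSS quantile (ties
included). Haplotype blocks are consumed as BED intervals (0-based,
half-open), never inferred from LD. Block membership of a SNP position P
uses the convention start ≤ P < end — a SNP at the block end coordinate is
excluded. A block is reported when it contains more than `min_block_snps`
(default 5, strict) member SNPs and at least one outlier.

## Synthetic data generator

The generator emulates the statistical structure the estimators assume:

- **Ancestral frequencies** p ~ Beta(0.8, 0.8) per site: a U-shaped
  frequency spectrum concentrating mass near the boundaries, a reasonable
  stand-in for a variant-site frequency distribution.
- **Stock drift**: Balding–Nichols, stock frequency
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F), mean p, variance F·p(1−p). F = 0
  short-circuits to p exactly. Default F = 0.05, which yields realized
  genome-wide pairwise F_ST around 0.02–0.03 — the range observed among
  real commercial stocks.
- **Planted selection**: non-overlapping regions (default five regions
  covering 1% of sites) where the four resistance-bred stocks'
  frequencies are shifted by +0.4 (clipped to [0,1]).
- **Pool sampling**: per pool and site, chromosome counts
  ~ Binomial(24, stock frequency) — the pool-size variance floor that
  pool-seq estimators must tolerate — then depth ~ Poisson(30), read
  counts ~ Binomial(depth, realized pool frequency), and a symmetric
  sequencing error (default 10⁻³) flipping each read to a uniformly chosen
  other base.
- **Design**: 8 stocks × 12 pools × 24 chromosomes at 30× mean depth,
  mirroring the real sequencing design (96 pools of 12 workers).
- **Haplotype blocks**: the chromosome is tiled with blocks of length
  uniform in [287, 17,663] bp, the observed real-data block-length range.

What it does **not** emulate: linkage and recombination (sites are
independent, so haplotype blocks here are coordinate containers, not LD
structures), indels and alignment artefacts, depth overdispersion beyond
Poisson, base-quality variation (a constant Q30 regime is assumed,
consistent with quality filtering upstream of counts), within-stock pool
relatedness (pools within a stock are exchangeable draws, whereas real
pools share queen lineages), and the monomorphic bulk of a real genome —
every simulated site is a candidate variant, which is why per-eligible-site
π (~0.29) is orders of magnitude above real per-bp genome-wide values
(~5×10⁻³). Passing tests therefore demonstrate estimator correctness and
pipeline behavior under the assumed sampling model, not robustness to
alignment artefacts or LD.

## Numerical conventions and degenerate inputs

- Coordinates: sync and VCF are 1-based; BED and all window/region
  intervals are 0-based half-open. Conversion happens only at module
  boundaries (property-tested at interval edges).
- Sync count order is A:T:C:G:N:del; N and deletion counts never enter
  coverage.
- Ties: fractional ranks average; top-quantile sets include ties at the
  cut; the elbow tie-breaks to the smallest k; major/minor allele ties
  break by base order (A, T, C, G).
- Empty windows, zero-SNP pairs, and zero-coverage frequencies are
  missing (NaN), never fabricated zeros.
- Determinism: every stochastic component consumes a numpy `SeedSequence`
  derived from the run seed; independent streams are used per stage so
  adding a stage never perturbs another's draws.

## Problem sizes

Default analysis sizes were chosen so a complete study — simulation,
diversity, 15 pairwise scans, structure and CSS on 50,000 sites × 96
pools — completes in well under a minute on a single core, while being
large enough for stable quantiles (a top-0.1% set of ~40 SNPs out of
~40,000) and percentile-based coverage caps. The cluster-recovery analysis
uses 24 pools × 3,000 sites; the null calibration uses 10,000 SNPs × 4
contrasts.

## Known limitations

- Diversity values are comparative, not absolute: the π/θ estimators skip
  the pooled-sampling bias corrections, and θ's lineage count ignores
  read-level resampling.
- The stock-specific SNP rule and the max-coverage interpretation are
  explicit choices among ambiguous readings (both configurable).
- The elbow rule always selects some k ≥ 2 on featureless AIC curves; use
  the AIC table, which is always written, when judging whether structure
  exists at all.
- VCF ingestion expects per-sample AD or AF; sites with neither are
  unsupported rather than guessed.
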