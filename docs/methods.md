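# Methods

This note documents the statistical procedures `epiland` implements,
the choices made where the design was genuinely open, what the
synthetic generators do and do not emulate, and the numerical details
that matter for reproducing results.

## Signals and the delta matrix

The pipeline starts from per-gene quantifications (normalized coverage
for six histone marks, TPM-like units for mRNA) in two housing
conditions, GH and SH, with ≥ 1 replicate each. Upstream normalization
(e.g. TMM between replicates and treatments) is assumed done; a
per-column median-scaling fallback (`median_scale`) is provided for
inputs that skipped it, but it is not a TMM replacement.

**Expressed-gene filter.** Genes are ranked by mean expression and the
top `ceil(fraction·G)` kept (default fraction 0.4). The ranking mean is
pooled over the two conditions by default — the natural symmetric
choice when the filter should not prefer either condition — with
per-condition ranking available via `rank_on`. Ties break
lexicographically by gene id so the selection is deterministic. The
expression unit is treated as opaque (TPM and FPKM behave identically
here). An advisory signal-to-noise report gives, for the genes below
the cutoff, the share whose within-treatment mean/sd (averaged over
conditions) is below 1; it never alters the filter.

**Delta matrix.** Per signal, the GH−SH difference of replicate means
is z-scored across the expressed genes. z-scoring uses the sample
standard deviation (ddof = 1), matching common statistical software and
making the 3-gene hand case (differences 1, 2, 3 → z = −1, 0, 1)
exact. A signal whose differences are constant has no z-scale and is
rejected by name. Column means are 0 and sds 1 to 1e−9 by
construction.

**Fold changes.** `log2fc = log2((GH + pc)/(SH + pc))` with pseudocount
default 0.5 expression units (guards division by zero; configurable).
The percent change used for TF filtering is symmetric,
`100·(max(r, 1/r) − 1)`, because "change in transcript levels" is
directionless: a 4/3 ratio either way is a 33.33% change. Direction is
carried only by the sign of log2fc.

## Clustering and stability

`StabilityKMeans` wraps Lloyd's algorithm with k-means++ seeding and
`n_init` restarts (best inertia wins); identical seeds give identical
labels. Empty clusters cannot survive — the solver relocates an empty
centroid to the farthest point, preserving k. The nominal k ≤ n/10
guideline for meaningful clusters is documented rather than enforced,
because the stability overlap metric is well defined (and unit-tested)
on tiny assignments.

**Choosing k.** Two criteria over a k range, both always returning the
full diagnostics curve:

* `bic`: hard-assignment spherical Gaussian with shared variance
  σ² = RSS/(n·d); BIC = −2·logL + (k·d + 1)·ln n, minimized.
* `elbow`: largest second difference of the inertia curve (interior k).

A selection is flagged `low_confidence` when the optimum is pinned at
the search boundary or shallow (BIC: neighboring values within 1% of
the curve range; elbow: peak second-difference less than 5× the median
absolute second difference). On featureless data the flag trips; on
separated planted data it does not.

**Stability.** N assignments are produced with seeds
`base_seed + 0 … N−1` (recorded for replay). For each unordered pair
(i, j), i < j, and each cluster c of assignment i, the record is the
maximum percent overlap of c with any cluster of assignment j,
`100·max_c′ |c∩c′|/|c|`. The denominator is the source cluster's size,
which makes "94% overlap" interpretable per cluster; sources come from
the lower-indexed assignment only, so there are exactly k·N(N−1)/2
records (8280 at N=46, k=8 — taking both orderings would double this).
The summary is the median record and the fraction above 99%. The
metric is invariant to cluster relabeling in either assignment.

**Profiles.** Per-cluster mean z per signal, with clusters re-labelled
1..k in increasing order of mean mRNA expression (pooled TPM when an
expression table is supplied, the mRNA z column otherwise), plus the
genes-per-cluster vector.

## Motif analysis

**PWMs.** Read from MEME minimal format. On construction a pseudocount
is mixed in row-wise, `(p + pc·bg)/(1 + pc)` (default pc 0.1 for
matrices built from counts; the MEME reader uses 1e−4 since files
already hold probabilities), so log-odds `log2(p/bg)` is finite
wherever the background is positive.

**Exact score p-values.** The null distribution of the log-odds score
of a background-distributed L-mer is computed by dynamic programming
over PWM columns with scores discretized to integer multiples of a
granularity (default 1e−3 bits; the worst-case accumulated rounding
L·γ/2 is checked against a cap and coarser settings are rejected with
a suggestion to refine). For L ≤ 6 the DP equals exhaustive 4^L
enumeration to 1e−9. The scan threshold for a requested p is the
smallest binned score whose exact tail probability does not exceed p;
comparisons happen in bin space, so the per-window hit probability
under the background equals the attained p exactly (verified by Monte
Carlo against exact binomial bounds).

**Scanning and counting.** Both strands of the TSS ± 500 bp window
(1001 bp, 0-based half-open, clipped-and-flagged at contig edges) are
scanned; windows containing N never match; overlapping hits all count,
so a palindromic site contributes 2 (once per strand) — deliberate and
documented, since strand preference is unknowable for a palindrome.
Counting is strand-symmetric: reverse-complementing every sequence
leaves counts unchanged.

**Enrichment.** Positional-concentration testing is replaced by
presence/absence within the fixed promoter window, which already
encodes the positional restriction: per cluster, the control set is an
equal number of genes sampled (seeded) without replacement from the
universe outside the cluster; per motif, a one-sided hypergeometric
test compares genes carrying ≥ 1 site in cluster vs control; p-values
are Bonferroni-adjusted over motifs (conservative, fitting the extreme
cutoff) and a motif is enriched at adjusted p < 1e−10. Total site
counts are reported alongside gene-level presence, since either
statistic can be of interest.

**TF filter.** Enriched motifs collapse to their TF gene; a TF is kept
if its gene is in the expressed set and shows ≥ 33.3% symmetric
transcript change. Motifs without a TF mapping are kept in a flagged
"unmapped" bin, excluded from the shortlist.

**Stepwise regression.** OLS (with intercept) of per-gene mRNA log
fold change on motif counts; the predictor with the largest coefficient
p is dropped repeatedly while any p ≥ the elimination threshold.
`alpha` (default 0.05) governs the reported +/− signs; `drop_alpha`
(default = alpha) is the elimination threshold, and setting it to 0.10
retains marginally significant predictors, rendered "(+)"/"(−)" —
keeping elimination and annotation as separate knobs is what makes a
marginal band representable at all. An AIC-guided mode
(`criterion="aic"`, drop least-significant-first while AIC improves)
is available. Perfectly collinear predictor pairs drop the later-listed
one with a warning before fitting. Reported: retained motifs with
coefficient/t/p/sign, r = √R² of the final fit, and the overall F-test.
A selection caveat worth knowing: under the null, *per-predictor*
retention tracks alpha, but backward elimination keeps the minimum of
the candidate p-values, so with 5 null predictors roughly 1 − 5·alpha
of runs retain nothing (not 1 − alpha).

## Gene-set statistics

Sign tests are exact binomial at p = 0.5; sidedness is an explicit
argument, never a default, because published values mix conventions
(14/15 one-sided → 0.000488 "0.0005"; 9/9 two-sided → 0.00391
"0.004"); two-sided is min(1, 2·smaller tail). Set comparisons default
to Welch's unequal-variance t (pooled-variance and rank-sum
alternatives available); identical constant inputs return statistic 0,
p = 1 rather than an undefined ratio; multiple signals are reported as
per-signal rows without cross-signal adjustment, matching per-mark
reporting. Fold-change correlation is Pearson on the gene-id
intersection (≥ 3 genes), with n reported.

## Sleep

A sleep bout is a maximal run of ≥ 5 consecutive zero-count minutes in
the 1-minute trace; the mask marks every minute inside a bout. Daytime
sleep sums mask minutes over [ZT0, ZT12) of a fully covered day; bouts
spanning lights-off are split by minute. The acclimation period
(default: the first recorded day) is trimmed *before* scoring, so a
bout spanning the trim boundary is truncated — a deliberate convention
the expected-sleep computation reproduces. Traces with gaps are
rejected; monitors emit dense data and imputation would silently
manufacture sleep. ΔSleep = mean(GH) − mean(SH) daytime sleep, with
per-group SEMs.

**Interaction test.** Because ΔSleep is a group-level difference
without per-fly replicates, the genotype × housing interaction on
per-fly daytime sleep is the operationalization of "the RNAi reduces
ΔSleep". The ANOVA uses sum-to-zero contrasts and Type III sums of
squares (full-vs-reduced comparisons); on balanced designs this equals
the classical decomposition term by term (tested to 1e−9 against a
hand-computed 2×2), and ≥ 2 replicates per cell are required, with
empty cells rejected by name.

## Synthetic generators

All generators are pure functions of (spec, seed).

**Landscape.** Each expressed gene gets a cluster (default K = 8,
uniform proportions); its 7-signal delta vector is the cluster mean
plus N(0, within_sd²). Cluster means are mutually orthogonal ±1
patterns (Hadamard rows, first column dropped), unit-normalized and
scaled by `separation·within_sd` (default separation 5 — clearly
separated, as the recovery suites require). Deltas are split into
GH/SH condition tables around per-gene baselines (uniform 30–80 units,
large enough that negative values never occur at the default effect
sizes) with replicate noise (sd 0.5, 3 replicates). A structureless
low-expression pool (gamma-distributed, mean ≈ 1, CV ≈ 2) makes the
expressed-gene filter meaningful; the default sizes, 5372 expressed of
13,430 total, mirror the study scale. Deltas are generated directly
rather than via read-level simulation — the pipeline's contract starts
at per-gene signals, and alignment/island calling are out of scope.

**Promoters.** Per gene and motif, planted site counts are
Poisson(1.2) capped at 6; log fold change is
`intercept + Σ β_m·count_m + N(0, 0.3)`. The default five motifs are
*synthetic stand-ins* for the shortlisted TFs (Hr38, cbt, CrebA, sr,
pho) with invented consensi — the CrebA stand-in is a CRE-like
palindrome on purpose, to exercise double-strand counting — and
coefficients (−0.3, −0.3, −0.2, +0.2, +0.25) mirroring the dominant
repressor signs. Sites (exact consensus, random strand,
non-overlapping) are inserted into background sequence with fly-like
composition (A=T=0.3, C=G=0.2); scanning can only add chance sites, so
scanned counts dominate the truth table.

**Activity.** A two-state per-minute Markov chain (awake/asleep) with
phase-dependent transition probabilities: day rates
GH 0.06/0.04 (fall-asleep/wake), SH 0.03/0.07 — stationary daytime
sleep ≈ 430 vs 215 min, a ΔSleep around 200 min, the magnitude of
control housing effects in this assay — night 0.15/0.01 for both, and
32 flies per group. An RNAi genotype shrinks both day-rate gaps toward
the midpoint by `delta_reduction` (default 0.5, halving the housing
effect). Awake minutes emit Poisson(λ = 2) counts (λ > 0 required);
asleep minutes emit 0. Scoring error from awake zero-minutes is below
1% of minutes at λ = 2.

**Exact planted ΔSleep.** The scored trace is a hidden Markov chain
(zero-count emission probability e^{−λ} awake, 1 asleep). Expected
scored daytime sleep is computed exactly as
Σ_t [P(count_t = 0) − P(t in a zero-run of length ≤ 4)], where each
exact-run probability P(nonzero, 0^l, nonzero) is a product of 2×2
transition matrices and emission diagonals, with the trim boundary and
trace edges handled as the scorer sees them. Recovery tests therefore
compare against the true expectation of the *pipeline's* statistic,
not the raw state occupancy (the DP is itself validated against Monte
Carlo within sampling error).

**What the generators do not emulate.** Read-level noise, mark
autocorrelation along the genome, non-spherical or overlapping
clusters, motif positional preference within the window, correlated
motif co-occurrence, circadian structure beyond the 12/12 square wave,
and inter-fly variability in sleep propensity. Passing recovery suites
show the procedures are correct and well-calibrated under the stated
models; they do not certify performance on real data where these
features matter.

## Problem sizes and numerics

Default suite sizes (chosen for tight feedback loops while keeping the
statistical checks meaningful): landscapes of 600–1000 genes for
k-recovery and stability (the full 5372/13,430 scale runs in the
acceptance script), 20 seeds for k-selection replication, 46 runs for
the stability-combinatorics check, 100–200 trials for regression
null/power, 10 seeds × 128 flies for behavioral end-to-end. Tolerances:
delta-matrix normalization 1e−9; DP-vs-enumeration 1e−9; balanced
ANOVA decomposition 1e−9; stochastic recoveries 3 SEM (4 SEM where the
oracle itself is Monte Carlo). Ties at equal PWM score all report;
score comparisons happen on integer bins to keep the hit probability
exactly the attained p. Seeds: stability run i uses base_seed + i; the
CLI threads one config seed through every stage; the acceptance script
derives child seeds from `--seed` via `SeedSequence`.

## Known limitations

* Enrichment replaces positional-concentration testing with windowed
  presence/absence; motifs enriched only through positional bias
  within the window would be missed.
* The BIC variant assumes spherical clusters with shared variance;
  elongated or heteroscedastic clusters can shift the chosen k (the
  diagnostics curve is always available for alternatives).
* Stepwise p-values are post-selection and should be read as
  descriptive, as in the tabulated-sign reporting convention, not as
  valid inferential error rates.
* The monitor reader expects dense DAM-style files; other logger
  formats need conversion.
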