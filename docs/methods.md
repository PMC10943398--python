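# Methods

This note records the statistical models the package implements, the
defaults it ships, the choices made where the design was genuinely open,
and what the synthetic benchmarks do and do not demonstrate.

## Differential expression

Expression is assumed to be approximately Gaussian per gene on the log2
scale, as for normalized microarray intensities. Batch correction is a
per-gene location adjustment: within each batch the gene's mean is shifted
to its grand mean, which equalizes batch means exactly, preserves the
grand mean, and leaves within-batch deviations untouched. This is
deliberately weaker than empirical-Bayes location–scale harmonization; it
makes the contract (`per-batch means equal within 1e-8`) checkable to
machine precision and suffices for additive batch offsets, which is what
the generator plants. Batches with fewer than two samples are rejected
rather than silently passed through.

The test statistic is a two-sample *t*. With `moderation=False` it is the
Welch unequal-variance form. With `moderation=True` (the default) the
pooled gene-wise variance s² with d = n₁+n₂−2 degrees of freedom is shrunk
toward a common prior, s²ᵖᵒˢᵗ = (d₀s₀² + d·s²)/(d₀+d), and the statistic is
referred to t on d₀+d degrees of freedom. The prior (d₀, s₀²) is fitted by
method of moments on log s²: the excess variance of log s² beyond
trigamma(d/2) identifies d₀ through a Newton inversion of the trigamma
function, and the location identifies s₀². If the observed spread of log
variances is no larger than sampling noise, d₀ = ∞ and all genes share
s₀². Setting the prior weight to zero recovers the classical pooled t
exactly, which is the degenerate case the unit tests pin at 1e-12.

Degenerate genes (zero variance in both groups, equal means) are assigned
t = 0, p = 1; zero variance with unequal means is treated as infinite
evidence (p = 0).

A gene is called differential when |log₂FC| > log₂(1.2) — the fold-change
threshold interpreted on the linear scale — and its Benjamini–Hochberg
adjusted p is below 0.05. The BH step-up is implemented directly (sort,
scale by n/rank, running minimum from the largest rank, cap at 1) and is
permutation-equivariant. A flag gates on the raw p instead for users who
read "P < 0.05" literally; adjusted is the default because FDR correction
is stated alongside the threshold.

## Dual biomarker selection

Both selectors standardize features internally, so any positive rescaling
of a gene column leaves selections unchanged.

*L1-logistic path.* The penalty grid is log-spaced over [10⁻³, 1]·λ_max
with λ_max = maxⱼ|xⱼ·(y−ȳ)|/n, the smallest penalty that zeroes every
coefficient at the null model. λ is chosen to minimize mean deviance over
seeded stratified folds (the minimum rule, not 1-SE), then the model is
refit on all samples and nonzero coefficients are reported. The convex
solve is scikit-learn's liblinear; grid construction, fold logic and the
deviance criterion are in-repo.

*SVM-RFE.* A linear SVM (C = 1) is fit on the surviving features; the
`elimination_step` features with the smallest squared weights are removed,
never past a single survivor; the ranking is the reverse removal order of
the all-sample pass. The retained subset size comes from **nested**
cross-validation: the elimination is re-run inside each training fold and
every visited size is scored on the held-out fold. Scoring prefixes of the
all-sample ranking instead would be selection-biased — the error curve
floors at zero before all informative features have entered, and the
ties-toward-smaller rule then truncates the panel; nested scoring is the
standard bias-free estimator and is what the planted-recovery benchmark
exercises. Ties in mean error still resolve toward the smaller size.

The key biomarker set is the plain intersection of the two selections.
Class imbalance is handled by stratified folds only; no reweighting, no
nonlinear kernels, no search beyond λ and subset size.

## Consensus subtyping

For each candidate k, H subsamples of ⌈p_item·n⌉ samples (defaults
H = 1000, p_item = 0.8; benchmarks use H = 100 for speed) are clustered by
agglomerative average linkage on 1 − Pearson correlation between samples,
and consensus(i,j) is the fraction of co-sampled runs in which i and j
co-clustered — defined as 0 for pairs never co-sampled. The area under the
consensus-value CDF equals 1 − mean consensus and is computed exactly.

k selection was a genuinely open design point. The delta-area elbow
(largest k whose relative area gain exceeds 0.1) is computed and exposed,
but it is not the default chooser: even on perfectly separated two-cluster
data the k = 3 consensus area keeps rising well past the threshold
(measured delta ≈ 0.15–0.25), because forcing a third cluster splits one
tight block differently across subsamples, so the largest-k rule
over-partitions clean data. The default chooser is therefore minimal
ambiguity — the PAC criterion, the proportion of off-diagonal consensus
values inside (0.1, 0.9), ties toward smaller k — which formalizes "the
CDF with the least fluctuation between 0 and 1" and returns k = 2 with
perfect label recovery on the two-blob benchmark. `chooser="delta_area"`
selects the threshold rule instead, and the chosen k can always be
overridden.

Final labels come from average-linkage clustering of 1 − consensus at the
chosen k. Subcluster contrasts (exactly two clusters) use the rank-sum
test per gene with BH adjustment. PCA display projects the
column-centred matrix onto its top right-singular directions.

## Immune-fraction correlation

Fractions are consumed, not estimated: the table carries a per-sample
deconvolution p-value and samples are filtered at p < 0.05 before any
statistics. Gene–cell association is Spearman rho on average ranks with
the t-approximation p-value; constant vectors give a flagged, excluded
record. P-values are BH-adjusted within each gene across cell types — a
conservative, simple convention; nothing in the upstream analysis dictates
the family. By default correlations are computed on case samples only
(matching the framing of biomarker–immunocyte correlations *in disease*),
with an all-samples mode available.

Group contrasts use the two-sided Wilcoxon rank-sum: exact null
enumeration when both groups have at most ten observations and the pooled
sample is tie-free, otherwise the tie-corrected normal approximation
without continuity correction (so that exactly balanced data give p = 1).
An all-identical pooled sample short-circuits to p = 1.

## ceRNA network

N is the number of distinct miRNAs in the union of both interaction
tables — the least ambiguous reading of "total miRNAs in the interaction
data". Candidates are all (lncRNA, key-gene mRNA) pairs sharing at least
one miRNA. The sharing tail is evaluated through the exact hypergeometric
survival function, never by simulation. Two conventions exist: the
printed formula sums the CDF to x (P(X > x)); the conventional
at-least-x tail sums to x−1. The printed form is the default because it is
the citable contract; it is never larger than the at-least form, strictly
smaller whenever P(X = x) > 0. Impossible combinatorial corners contribute
zero-probability terms rather than exceptions.

Retention requires the hypergeometric p below 0.01 (0.05 acceptable via
flag; both thresholds appear in the source material) **and** Pearson
r > 0.3 at p < 0.01 across all samples of the co-expression matrix. No
multiple-testing correction is applied to the hypergeometric p by default
(raw thresholds are the stated procedure); a BH option exists. The
retained pairs, their shared miRNAs, the miRNA–target edges and the
competing lncRNA–mRNA links form an undirected typed graph; hub ranking
sorts lncRNA nodes by degree, then unnormalized shortest-path betweenness
(equal-length paths split evenly), then identifier.

## Diagnostics

AUC is the Mann–Whitney rank statistic (average ranks, so ties count 1/2);
the ROC polyline swept over all distinct thresholds has exactly this
trapezoidal area, and the test suite holds the two computations together
at 1e-12. The combined panel score is the linear predictor of a logistic
model with a vanishing ridge (C = 10⁶), which keeps the fit defined under
perfect separation while being numerically indistinguishable from the
unpenalised fit otherwise; a model-free mean-of-standardized-expression
score (genes oriented by their training-case direction) is available as an
alternative. Validation refits per-cohort by default, mirroring
per-cohort ROC presentation; reusing discovery coefficients is a caller
choice (pass the discovery matrix as training data).

## Synthetic-data generators

The generators define the study conditions for every benchmark and are
pure functions of their arguments including the seed.

*Cohort.* Baseline gene means are N(7, 2) on the log2 scale with i.i.d.
N(0, noise_sd) noise — typical microarray intensities; nothing heavier-
tailed is attempted. A `de_fraction` share of genes receives a signed
case shift with magnitude N(lfc_mean, 0.1·lfc_mean) clipped below at
0.1·lfc_mean, a modest spread that keeps planted effects detectable at the
stated benchmark sizes without making them uniform. Samples are assigned
round-robin to batches, each with additive per-gene N(0, batch_sd)
offsets. The curated-style panel holds 63 genes including 6 planted key
genes (a curated-panel/biomarker-panel scale), and the key genes separate
the cases into two planted subclusters via an alternating-sign shift of
2.0 log2 units applied **symmetrically** (−s/2 and +s/2) so that the case
mean — and with it every truth invariant tying key genes to the planted
case/control effects — is preserved exactly. A validation-cohort helper
replants the same signed effects with fresh samples and noise.

*Fractions.* Rows are symmetric Dirichlet (α = 1) over 22 cell types; the
designated cell type's mass is multiplied by exp(link_strength·z) of the
standardized linked gene and the row renormalized. This produces a tunable
rank correlation without claiming any deconvolution model; deconvolution
p-values are drawn Uniform(0, 0.05) so synthetic samples pass the filter
unless the caller overwrites them.

*Interactions.* Each planted (lncRNA, mRNA) pair gets a dedicated set of
`shared_per_planted` miRNAs wired to both partners; every other edge
appears independently at `background_rate`. Partner expression is
bivariate normal at the target Pearson r over 60 samples; everything else
is independent N(0, 1).

What passing benchmarks do *not* show: robustness to probe-level
artifacts, non-Gaussian intensity distributions, correlated gene modules,
confounded (non-additive or group-unbalanced) batch structure, count
noise, or biased interaction databases. Real cohorts can violate any of
these; the benchmarks certify the machinery, not the biology.

## Problem sizes

The default pytest run exercises exact small-universe enumerations (every
hypergeometric quadruple with N ≤ 12; every tie-free rank-sum split with
group sizes ≤ 7; 100 random graphs with ≤ 8 nodes against path-enumeration
betweenness), 1,000-vector BH and AUC identity sweeps, a 10,000-gene null
calibration at n = 10 per group, and 20-seed recovery benchmarks (6
planted genes among 200 at n = 60 per class; 5 planted ceRNA pairs over
200 miRNAs). The acceptance script runs the full workflow on a
210-case/99-control, 2,000-gene cohort. These sizes were chosen so the
whole suite completes in a few minutes while the enumerated oracles remain
exhaustive.

## Known limitations

- Batch correction is location-only; variance heterogeneity across
  batches is not harmonized.
- The moderated t assumes a common variance prior across all genes; no
  intensity-dependent trend is fitted.
- Consensus clustering resamples samples only (no gene resampling), and
  contrast statistics are defined for exactly two subclusters.
- The hypergeometric test conditions on the observed interaction tables;
  database ascertainment bias propagates directly into N, n and m.
- Surrogate-variable estimation, deconvolution itself, enrichment
  analysis and single-cell processing are out of scope; their outputs are
  inputs here.
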