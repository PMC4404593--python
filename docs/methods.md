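# Methods

This note documents the models, the tunable parameters, the numerical
choices, and what the synthetic cohorts do and do not establish.

## Classification model

Each tumor class c is modeled as a multivariate normal over the
selected probes; classification is the Bayes rule
p(c | x) ∝ p(x | c) π_c with π_c the class frequencies (maximum
likelihood), and p(x) = Σ_c p(x | c) π_c exposed alongside the
posterior. LDA shares one covariance across classes; QDA fits one per
class.

**Covariance structure.** With hundreds of selected probes and a few
dozen samples per class, a full per-class covariance is singular, so
the default is diagonal: probe-wise ML variances (pooled over classes
for LDA, per class for QDA, divisor n rather than n−1), floored at
ε = 1e-6 to keep log-densities finite on degenerate probes. A full
covariance shrunk toward the scaled identity,
Σ ← (1−λ)S + λ(tr S/p)I with λ = 0.1 by default, is available for
low-dimensional inputs. All density arithmetic is in log space
(log-sum-exp for mixtures); at hundreds of probes the densities
themselves underflow double precision by hundreds of orders of
magnitude.

**Feature selection and honest accuracy.** Per-probe one-way ANOVA F
against F(K−1, N−K). The p-value cutoff is chosen from the grid
1e-2 … 1e-12 by leave-one-out cross-validation in which the F-test is
recomputed on each split's training samples — selection outside the
loop would leak the held-out sample into the signature. Ties between
cutoffs break toward the stricter one (smaller signature). If a split
selects no probe at some cutoff, that split falls back to the
largest-prior class; at equal class sizes this fallback is
systematically wrong for the held-out sample (its own class is one
sample short), so cutoffs too strict for the data score near zero and
are never chosen. Constant probes get F = 0, p = 1 by convention.

**Sex-specific priors.** At prediction time the priors of classes
impossible for the sample's sex (default map: ovary → F, cervix → F,
prostate → M; configurable) are set to zero and the remainder
renormalized — equivalent to conditioning the posterior on the
allowed classes. Samples of unknown sex are not masked. Posterior
ties break to the lowest class index with a logged warning.

## Outlier score

OS = −log p(x), natural log, under the QDA mixture. Scores for
samples of known class are computed leave-one-out (the class moments
are downdated before scoring, so a sample never supports its own
density); unknown-class samples are scored against the full model,
which by ML-invariance is unchanged under duplication of the cohort.
The absolute scale grows linearly with the probe count and is
meaningless across cohorts; only within-cohort comparisons are
interpreted. Whether the pooled-normal class joins the model is a
flag (`include_normal`, default on).

Samples are ranked into equal-frequency bins (default 10; remainder
samples go one each to the lowest-score bins — equal-frequency rather
than equal-width stabilizes the per-bin error estimate), and a
least-squares polynomial (default degree 2) of error rate on median
bin score summarizes the score-to-risk relationship, clipped to
[0, 1] at evaluation. Normal-tissue samples are excluded from the
bins by default: the pooled class is too heterogeneous for its scores
to be comparable.

## Paired differential expression

Per probe, OLS on the additive fixed-effects design
expression = μ + class + group, with the two-sided t test of the
group (CUP − MOKO) coefficient at n − K − 1 residual degrees of
freedom. Any per-class constant offset lies in the span of the class
dummies and cannot move the group estimate (verified to 1e-10).
Classes lacking either group are excluded with a log notice — the
contrast is not estimable there. Variances are probe-wise;
groups are unweighted; no moderation/shrinkage of the residual
variance is applied (at the cohort sizes simulated here, ~200
residual df, moderation would change little). FDR is
Benjamini-Hochberg (no specific procedure is canonical for this
analysis; BH is the field default). The core-set cutoff defaults to
p < 1e-8, appropriate for cohorts of a couple of thousand samples;
smaller studies should relax it (the examples use 1e-6 at ~240
samples).

## Enrichment

**Overlap.** Upper-tail hypergeometric P(X ≥ k) with the universe
defined as all annotated genes on the (filtered) matrix, sets
intersected with the universe first, BH across sets. A web-tool
universe from a particular annotation release is not reproducible
here; defining the universe from the data is the defensible
alternative and is what the k/K columns are computed against.

**GSEA.** Genes (probes collapsed by mean per symbol) are ranked by
signal-to-noise (m₁−m₂)/(s₁+s₂), each sd floored at 0.2·|mean| (0.2
absolute at zero mean). The ES is the extremum of the weighted KS
running sum (weight 1; hits advance by |stat|^w normalized, misses
retreat by 1/(N−N_hit)). The null permutes group labels when both
groups have ≥ 7 samples, otherwise random gene sets of the same size
(logged). p is the same-sign tail fraction; NES divides ES by the
mean |same-sign permuted ES|. Note that with weight 1 the ES depends
on the ranking statistic's magnitudes, so it is invariant to monotone
transformations only at weight 0.

**Instability score.** Signature symbols are translated to probes,
the top half by across-sample variance kept (fraction configurable;
redundant probes that do not respond dilute the signal), retained
probes standardized to mean 0 / variance 1, and the per-sample mean
taken. The score is therefore invariant to per-probe constants and
has cohort mean ≈ 0. Its Pearson correlation with the outlier score
(two-sided t-transform p) is computed on tumor samples.

## Synthetic cohorts

The generator emulates the statistical shape of a multi-class RMA
cohort: values are Gaussian per probe on the log2 scale (baseline
7.0), each class elevates its signature block (default 30 probes by
2.0 log2 units against noise sd 1.0), metastases add 0.5 on the same
block, and the default design has 5 classes × (40 primaries + 40
metastases) + 40 CUP + 20 normals over 2000 probes. CUPs are drawn
*from* a known class — the truth label a classifier should recover —
with all probe sds multiplied by 2.0 and a 180-probe instability
signature up-shifted by 1.0 (0.3 in metastases, so instability orders
normal < primary < metastasis < CUP). Probes map 1–2 per gene (30% of
genes carry two probes) to exercise probe/gene translation. Decoy
gene sets are uniform draws from the whole gene universe, which makes
their overlap with any fixed query exactly hypergeometric — the
property the decoy false-positive checks rely on. Sex is Bernoulli
(default 0.5 female) except in sex-restricted classes.

Where magnitudes are not externally fixed, they were chosen once for
realism and diagnostic power: the 2.0 class effect makes classes
separable the way well-differentiated tumor classes are; the CUP
dispersion factor 2.0 makes the outlier-score gap qualitatively
clear without being numerically matched to any real cohort; the
1.5-log2 effect used in the differential-expression checks gives
~99% theoretical power at p < 1e-8 for 40 vs 160 samples, so the
observed recovery rate is a sharp diagnostic. The acceptance script
runs cohorts of 400–440 samples × 2000–2400 probes, sizes at which
every stage completes in seconds while keeping ≥ 2000 null probes for
calibration checks.

**What passing on synthetic data does not show.** Real cohorts have
correlated probes, batch effects, heteroscedastic noise, mislabeled
samples and classes of very unequal size; none are simulated. The
generator validates the *machinery* — that each stage recovers what
was planted and stays calibrated under its null — not clinical
performance. Two known consequences on the default cohort: the
classifier is error-free, so the error-vs-score bins are all zero and
the score-to-risk trend is computed on a constant profile (treated as
trend 0); and because LOOCV splits share their chance-selected
features, the null (zero-effect) LOOCV accuracy is far more variable
than a binomial count would suggest — a point to keep in mind when
judging chance-level behavior from a single cohort.

## Degenerate inputs and tie-breaks

Zero-variance probes: rejected by `standardize_probes` (named in the
error), silently removed by any positive IQR threshold, floored at ε
in discriminant fits. Quartiles use linear interpolation between
order statistics. UPGMA uses Euclidean distance on the given values
by default (correlation distance available); merge heights are
non-decreasing by construction. Sorting ties anywhere use stable
(mergesort) order so results are permutation-stable.
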