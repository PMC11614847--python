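# Methods

This note documents the statistical models inside `decombine`, the
defaults and why they were chosen, what the synthetic benchmark does and
does not emulate, and the numerical conventions that keep every output
finite and reproducible.

## Data model and conventions

Input is a raw count matrix (genes x samples, nonnegative integers) and a
metadata table with a two-level condition. The second level named in the
contrast is always the **test class**: its mean forms the numerator of
every log2 fold change. Multi-level designs are out of scope; extra
metadata columns are carried but ignored by the engines. Wherever a ratio
of means is formed, a pseudo-count of 0.125 is added to both means so the
log2FC is finite even when one group is all zero.

## Filtering

Three alternatives, applied once and shared by all engines:

- `rowsums` (default for user data): keep genes with total count >= 10.
- `by_expression`: the expression-aware rule — keep a gene iff its CPM
  exceeds `min_count / median library size (millions)` in at least k
  samples, k being the smallest group size softened beyond `large_n`
  (`min_count=10, min_total=15, large_n=10, min_prop=0.7`), and its total
  count is >= 15. The benchmark uses this filter.
- `variance`: keep genes by variance of log2-CPM (with 0.5 pseudo-count),
  either above a floor or the top-n most variable (ties broken by gene
  id). Operating on log-CPM rather than raw counts makes the criterion
  robust to sequencing depth.

All filters are idempotent and only ever drop genes.

## Normalization

**TMM**: the reference sample is the one whose upper-quartile CPM is
closest to the mean upper-quartile. Per sample, log2 expression ratios M
against the reference (genes positive in both) are trimmed by rank — 30%
of the M distribution and 5% of the average-abundance A distribution —
and averaged with inverse asymptotic-binomial-variance weights; factors
are rescaled to geometric mean 1 and multiply library sizes into
effective library sizes. Trim fractions are exposed but default to the
published 0.30/0.05.

**Median-of-ratios**: size factor = median over all-positive genes of the
ratio to a geometric-mean pseudo-reference. Genes with any zero are
excluded from the pseudo-reference (standard convention). The factor
absorbs depth itself; for CPM purposes the effective library size is
`factor x geometric-mean library size` so scales stay comparable.

## The four engines

All engines receive the same filtered matrix and return the same table
(`base_mean, log2_fc, stat, p_value, padj`), one row per gene, same
order. Engines are simplified but statistically faithful implementations
of the four canonical approaches; bit-parity with any existing package is
not claimed — null calibration, power ordering and fold-change recovery
are the contract, and the test suite asserts exactly those.

### NB exact conditional test (`nb_exact`)

Counts are scaled to a common (geometric-mean) effective library size. A
**common dispersion** maximizes the summed conditional NB likelihood
(conditioning removes the group means as nuisance). Per-gene **tagwise**
dispersions are moment estimates shrunk toward the common value with a
prior weight of 10 degrees of freedom (`prior_df`, exposed): with m
samples, `phi_tag = (d phi_moment + 10 phi_common) / (d + 10)`, d = m - 2.
Conditioning on a gene's total, the test-class sum follows a
beta-binomial(t, n1/phi, n2/phi) law; the two-sided p sums the
probabilities of all splits no more likely than the observed one. For
totals above 5,000 a moment-matched normal approximation with continuity
correction is used (the beta-binomial is already near-Gaussian there);
below, the enumeration is exact. As dispersion approaches zero the law
degenerates to the conditional binomial (the Poisson two-sample test),
implemented as a special case below `phi < 1e-8`.

### Precision-weighted moderated t (`voom_limma`)

Log2-CPM (prior 0.5) is modelled linearly per gene. A first unweighted
pass gives residual standard deviations whose square roots are smoothed
by lowess (span 0.5) against average log2 count; each observation's
weight is the inverse fourth power of the trend at its fitted log-count.
The weighted two-group fit has a closed form. Residual variances are then
squeezed toward a prior estimated by method of moments on log variances
(the scaled-F model): the prior degrees of freedom d0 solve a trigamma
equation (Newton iteration). The moderated t uses
`s~2 = (d0 s0^2 + d s^2)/(d0 + d)` with d0 + d degrees of freedom. When
the observed variances show no heterogeneity beyond chi-square sampling
noise (d0 infinite) the prior degenerates to the geometric mean of the
observed variances, making moderation an exact fixed point in the
equal-variance case.

### NB GLM Wald test (`nb_wald`)

Median-of-ratios size factors enter a log-link NB GLM with two
coefficients as offsets. Per-gene dispersion is maximized by an
elementwise golden-section search over log-dispersion in [1e-8, 20] with
the **Cox–Reid adjustment** (-0.5 log det X'WX), which removes the
downward bias of the plain MLE — without it a planted dispersion trend is
recovered ~20% low. A parametric trend `alpha(mu) = a0 + a1/mu` is fit
across genes by iteratively reweighted least squares with gamma-style
weights (1/fitted^2), dropping genes whose ratio to the fit leaves
[1e-4, 15]. Log-dispersions are then shrunk MAP-style toward the trend
with prior variance `max(mad^2(log residuals) - trigamma((m-2)/2), 0.25)`;
genes more than 2 log2 units above the trend are dispersion outliers and
keep their (adjusted) MLE. The final IRLS fit (closed-form 2x2 solve per
gene, vectorized across genes) gives the Wald z for the condition
coefficient; log2FC = beta / ln 2.

### Variance-component score test (`score_test`)

On centered log2-CPM y and centered condition indicator x,
`Q = (sum y x)^2 / (sigma^2 sum x^2)` with sigma^2 the residual variance
(m - 2 denominator); asymptotic p from chi-square(1). With `n_perm > 0`
the null is taken over label permutations instead: all distinct
reassignments are enumerated when there are at most 10,000 (note the
squared statistic is invariant to complementing the labels, so the
smallest achievable p over C reassignments is 2/C), otherwise `n_perm`
reassignments are sampled from the run seed. The asymptotic variant is
the default; at small n it is mildly conservative/liberal depending on
the count distribution, which the calibration tests quantify. Constant
genes get p = 1 and log2FC = 0 by convention.

### Wilcoxon rank-sum (`run_wilcoxon`)

Per-gene two-sided rank-sum test on CPM. The exact null distribution is
used when both groups have at most 25 samples and the gene has no tied
values; otherwise the normal approximation with tie and continuity
corrections. Reported alongside the four engines (it is a large-cohort
specialist; at n = 3 its smallest achievable p is 0.1, so it calls
nothing after multiplicity adjustment — expected, not a defect).

## Combination and calling

Engine p-values are clipped to [1e-300, 1 - 1e-16] before transforms.
Two-sided p-values are fused directly, with no direction alignment; sign
discordance between engines is surfaced as a per-gene count. Lancaster
weights default to 2 for every engine (reducing to Fisher) because no
principled per-engine weighting is available a priori; they are
configurable. Wilkinson defaults to r = 1 (the Tippett minimum-p rule).
BH adjustment runs per combiner across the full filtered gene universe.
A DE call requires `padj <= 0.05` AND `|mean log2FC| >= 1` (both bounds
inclusive; thresholds configurable). Max-P lists genes called by all four
engines at the same thresholds, carrying their maximum raw p.

Two caveats are inherent to this family of pipelines and deliberately
reproduced rather than "fixed": (i) the engines are positively dependent
(same data), so combined p-values are anti-conservative in absolute
terms; the benchmark quantifies the practical false-positive cost.
(ii) the Bonferroni–Holm "combiner" is a step-down multiplicity bound,
not an exact transform — its output is sub-uniform (conservative) under
the null, unlike the other five, whose outputs are exactly uniform for
independent uniform inputs.

## Cook's distance screening

For every (gene, sample) cell, `D = (r_pearson^2 / p) h/(1-h)^2` from the
NB GLM fit (p = 2 coefficients), with the flag threshold at the 99th
percentile of F(p, m - p). The pipeline screens against the **trend**
dispersion of similarly expressed genes rather than the gene's own
estimate: a gross count outlier inflates its own gene's dispersion (and
the >2-log2 outlier rule then keeps that inflated estimate), which would
otherwise mask the very cell the screen exists to find. Flags are
reported, never applied; an opt-in mode sets flagged genes' Wald p to
missing. Corrupted cells on low-count genes stay within NB noise and are
legitimately not flagged. With m - p <= 0 the screen is skipped.

## Synthetic benchmark

`simulate_dataset` draws per-gene baselines `log2 mu ~ Normal(6, 2.5)`
truncated to `mu >= 1` and dispersions `phi = (0.05 + 2.5/mu) x
LogNormal(0, 0.3)` — a parametric stand-in reproducing the canonical
mean–dispersion decay of bulk RNA-seq. DE genes are chosen uniformly
without replacement in exact numbers, directions assigned in exact
rounded proportions (so configured splits are machine-checkable), and the
test-class mean multiplied or divided by `S = 1.5 + Exp(1)`. Counts are
NB draws at per-sample depth factors Uniform(0.7, 1.4). Outlier modes:
`single` multiplies one randomly chosen cell of 10% of genes by
Uniform(5, 10); `random` multiplies every cell independently with
probability 5%. The RNG stream derives from (seed, preset, replicate), so
replicates are independent and exactly reproducible.

The nine presets cover: a null dataset; 10% or 32% DE genes with balanced
or fully one-sided direction; and the null/balanced settings with single
or random outliers — all at 12,500 genes. The `large` preset has 100
samples per group, 20,000 genes, 10% DE split 40/60 between directions.

What the generator does **not** emulate: empirical baseline distributions
from real tissues, gene-length and GC effects, correlated genes, batch
structure, or library-preparation artifacts. Passing benchmarks therefore
demonstrate correct statistical behaviour under the NB model, not
end-to-end performance on any particular real dataset.

Evaluation restricts to genes surviving the expression filter; a call on
a truly-DE gene is a true positive regardless of direction (a
direction-aware mode exists). Metrics: sensitivity, specificity,
precision, F1, MCC, with 0/0 ratios defined as 0.

## Problem sizes in tests

The statistical test suite runs the full 12,500-gene medium-cohort
designs where calibration is asserted, and scaled-down 2,000–3,000-gene
variants (with the DE fraction preserved) where only orderings or
contracts are asserted; the small-cohort sensitivity comparison uses
presets 2 and 7 at 3,000 genes and five replicates. These sizes keep the
whole suite to a few minutes while leaving every assertion at its stated
tolerance.

## Known limitations

- Two-level contrasts only; no covariates, interactions or random
  effects.
- Engines are simplified reimplementations: no quasi-likelihood F-test,
  no independent filtering of the padj step, no fold-change shrinkage.
- No dependence-corrected combination (Brown/Kost); see the caveat above.
- The exact test's large-total branch mixes a probability-mass-ordered
  two-sided rule (exact path) with a 2 x min(tails) rule (normal path);
  the discontinuity at the threshold is negligible at those totals.
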