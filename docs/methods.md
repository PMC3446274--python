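# Methods

## Problem setting

The package analyses case-control DNA-methylation matrices (CpGs x samples,
beta-values in (0,1)) from prospective designs: samples are collected from
morphologically normal tissue, and "cases" are individuals who later develop
neoplasia. The working hypothesis is that risk is carried not by shifts in
*mean* methylation but by increased *variability*: at risk-associated CpGs a
small minority of case samples acquire outlier methylation gains of roughly
0.2-0.3 beta, which inflate the case-group variance while barely moving the
group mean. The pipeline therefore (i) detects differentially variable CpGs,
(ii) intersects them with age-hypermethylated CpGs to form candidate risk
CpGs, and (iii) scores samples by counting outlier "methylation hits" over
the risk CpGs in a robust, scale-free basis.

## Differential variability and differential methylation

For each CpG, beta-values are first linearly adjusted for age *within each
phenotype* (ordinary least squares of beta on age; residuals with the group
mean re-added), so that age drift does not masquerade as case/control
variability. Variances are then compared with the two-group Bartlett test

    T = [(N-2) ln s_p^2 - (n1-1) ln s1^2 - (n0-1) ln s0^2] / C,

with the standard small-sample correction C and a chi-square(1) tail. The
per-CpG output records the case/control variance ratio, its log2 (the
b-statistic), the Bartlett p and q. Mean differences are tested with a Welch
t-test (unequal variances is the only safe assumption when the object of
study is variance inequality itself); mean differences are always reported
in beta units. An option runs the variance test on the R = beta/(1-beta)
ratio scale, since beta-values are heteroscedastic; beta is the default.
(R reconstructs the methylated/unmethylated intensity ratio from beta alone;
it ignores the small denominator offset used by array chemistry, whose
effect is unquantified here.)
Bartlett's statistic assumes approximate normality within groups; on real
(skewed, bimodal) methylation data its null is only approximately
chi-square, which is one reason a q-value layer and a permutation facility
are provided.

Caveat on zero variance: a group with exactly zero variance but a varying
partner group yields T = +inf and p = 0; if both groups are constant the CpG
is flagged untestable (p = NA) rather than raising.

## Age association

CpGs gaining (or losing) methylation with age are found by per-CpG OLS of
beta on age with case/control status as an additive covariate, so the age
slope is estimated net of phenotype. This supervised regression replaces
latent-factor adjustment deliberately: it is transparent, fast, exactly
reproducible, and the covariates of interest (age, status) are observed.
The cost is that unobserved confounders (batch, cell composition) are not
absorbed; on arrays where those matter the vCpG ranking (below) is the
intended diagnostic. A CpG is "age-hypermethylated" iff its slope is
positive.

## q-values

False-discovery rates use Storey q-values: the Benjamini-Hochberg step-up
scaled by an estimate of the null proportion pi0. pi0 is the cubic-polynomial
smoother of pi0(lambda) = #{p > lambda}/(m(1-lambda)) over lambda =
0.05, 0.10, ..., 0.95, evaluated at lambda = 0.95. The estimate falls back
to pi0 = 1 (pure BH) when fewer than 100 p-values are supplied or the fit
leaves (0, 1]. q-values are monotone in p and NA p-values propagate.

## COPA basis and the risk score

Outliers must be defined in a way that is comparable across CpGs with very
different baseline levels and noise. The COPA (cancer outlier profile
analysis) transformation is the robust z-score

    c = (beta - median) / (1.4826 * MAD),

with the median and the raw median absolute deviation estimated on
*training samples only* and frozen for any later data. 1.4826 makes the MAD
a consistent estimate of the standard deviation under normality, so c is
interpretable in "robust standard deviations": typical samples score |c| < 1
and methylation outliers score above ~5. Because the median and MAD are
equivariant under per-CpG affine maps, COPA scores — and therefore all risk
scores — are invariant under per-CpG linear recalibration applied
consistently to training and test data (verified to 1e-10 in the tests).
CpGs whose training MAD is zero cannot be scaled and are excluded from
candidacy.

A trained model is (risk CpG list, frozen medians/MADs, threshold t,
scale). A sample's risk score is the fraction of risk CpGs whose COPA value
strictly exceeds t ("methylation hits"); a value exactly at t is not a hit
(an arbitrary but fixed convention). Scores are exact rational fractions
n_hits / n_used. At scoring time up to 10% of risk CpGs may be absent from
the supplied matrix; the denominator is then the number actually used
(cross-platform tolerance without silently inflating scores); more than 10%
absent is an error.

### Beta-scale variant

When outliers dominate a cohort (e.g. most cancers hemi- or fully
methylated at risk CpGs), the MAD itself inflates and COPA scores compress.
The beta-scale variant declares a hit when beta minus the *training median*
exceeds a threshold in beta units (default 0.2, the magnitude of the
outlier gains the score is designed around) and recovers discrimination in
that regime.

## Candidate selection and cross-validated optimisation

Candidate risk CpGs are the intersection {Bartlett q < fdr_dv, variance
ratio > 1} AND {age q < fdr_age, slope > 0}, minus COPA-unusable CpGs,
ordered by Bartlett p-value (ties broken by CpG identifier; every ranking
in the package uses this deterministic tie-break). Both FDR cutoffs default
to 0.05.

Training runs a stratified, seeded 10-fold internal cross-validation. In
each fold all statistics — variance and age tests, q-values, candidate
ranking and COPA parameters — are re-estimated on the fold's training part
only (no leakage; the alternative of re-using a full-cohort age-CpG list
was rejected on that ground). For every pair (threshold t, set size s) on
the grids, the held-out samples are scored with the top-s candidates and
the fold AUC recorded. The pair maximising the mean cross-validated AUC is
selected, with ties resolved toward smaller s, then smaller t (prefer the
simpler model and the more inclusive threshold). The final model re-fits
candidates and COPA parameters on the full training set and keeps the top
s* CpGs with threshold t*.

Default grids: thresholds {2, 3, 4, 5, 7, 10} in COPA units (spanning the
"outlier" bands; {0.1, 0.15, 0.2, 0.25, 0.3} on the beta scale) and set
sizes {25, 50, 100, 140, 200, all candidates}.

Two CV AUC summaries are recorded in `training_meta`: `cv_mean_auc`, the CV
AUC of the selected pair (a maximum over the grid, hence optimism-biased
upward — about 0.55-0.6 on label-permuted data), and `cv_grid_mean_auc`,
the grid average, which is the calibrated quantity that sits at 0.5 under
the null.

### Fallback when nothing is genome-wide significant

On modest training sets, mean-methylation statistics rarely clear an FDR of
0.05 (that weakness is the method's motivating contrast), and on
label-permuted data neither do variance statistics. So that the comparator
and null analyses remain defined, the estimators fall back — only when the
FDR filter selects nothing — to the top-200 direction-consistent CpGs by
ranking p-value (200 = the largest finite entry of the default size grid).
The strict functional API `select_candidates` keeps the hard error.

### Mean-methylation comparator

`MeanMethylationClassifier` swaps exactly one component: candidates are
selected by t-test q-value (q_t < fdr_dm, positive mean difference, ordered
by t-test p). Cross-validation, COPA basis, scoring and grids are shared
with the variability-based classifier, so performance differences isolate
the ranking statistic.

## Evaluation

AUC is the tie-corrected Mann-Whitney estimator (equivalent to the C-index
for binary outcomes); ROC curves come from a threshold sweep; confidence
intervals from a stratified percentile bootstrap (2,000 resamples, seeded),
widened if necessary to contain the point estimate. `repeated_holdout`
draws stratified train/test partitions (train fraction 2/3 by default),
trains each algorithm on the training part only and records held-out AUCs;
algorithms are compared against chance (signed-rank vs 0.5) and against
each other (paired signed-rank). Partitions whose training fails are
excluded and counted; more than 20% failures is an error.

## Enrichment

One-tailed Fisher's exact tests (hypergeometric upper tail) measure
category enrichment, with the Haldane-Anscombe 0.5 correction applied to
the odds ratio when a cell is zero (flagged in the output) and a
Woolf-logit 95% CI. The relative odds ratio ROR = OR(category among top-k
hypervariable)/OR(category among top-k hypovariable) gets its null from
re-ranking after random label permutations, with the add-one permutation
p-value (1 + #{null >= observed})/(1 + n_perm), which can never be zero.
The exact binomial skew test doubles the smaller tail, capped at 1.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with full ground
truth. Defaults (the study conditions used throughout the tests):

| parameter | default | meaning |
|---|---|---|
| n_cases / n_controls | 75 / 77 | prospective cohort sizes |
| n_cpgs | 20,000 | array-scale CpG count |
| n_risk | 500 | outlier-contaminated risk CpGs |
| n_age | 1,000 | age-drifting CpGs (risk CpGs are a subset) |
| n_vcpg | 500 | large-spread phenotype-independent CpGs |
| outlier_fraction | 0.15 | cases hit per risk CpG |
| outlier_shift_range | (0.2, 0.3) | beta gain per hit |
| age_range | (19, 55) years | uniform ages, both phenotypes |
| age_slope_range | (0.002, 0.006) beta/yr | drift magnitude |
| age_hyper_fraction | 0.61 | non-risk age CpGs gaining methylation |
| risk_beta_shape | Beta(2, 18) | low-methylation baseline (mean 0.1) |
| background_mean_range / noise_concentration | (0.1, 0.9) / 100 | background Beta baselines |

Risk CpGs sit on a low-methylation Beta(2,18) baseline; in case samples
only, a Bernoulli(0.15) subset gains Uniform(0.2, 0.3). This yields a
variance ratio near 3 with a mean difference of only ~0.0375 — large
variance signal, weak mean signal. Risk CpGs also drift upward with age, so
they satisfy both arms of the candidate definition. vCpGs are Uniform(0.05,
0.95) across all samples (range > 0.8). The `cancer_bimodal` regime instead
makes risk CpGs hemi- (0.5) or fully (0.9) methylated in ~70% of cases,
the regime in which COPA scores compress and the beta-scale score is
preferable. Ages are drawn independently of phenotype (an age-matched
design); HPV status is random with no methylation effect, so HPV adjustment
is a no-op robustness check.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: outlier hits are independent across CpGs
within a sample, whereas in real cohorts at-risk individuals carry
correlated hits across many CpGs and other cases carry none. Independence
makes the risk score average over 500 weak signals and pushes held-out AUCs
near 1.0; real prospective discrimination is far more modest. Probe
chemistry (type I/II), batch/chip effects, cell-composition confounding and
HPV-dependent methylation are likewise not simulated.

## Numerical conventions and degenerate inputs

* beta-values exactly 0 or 1 are clipped to [1e-6, 1 - 1e-6] so ratio
  scales stay finite; conversions refuse un-clipped boundary values.
* Missing values: CpGs with > 20% missing samples can be dropped by a
  documented filter; otherwise missing entries are excluded pairwise from
  means/variances, never imputed.
* Constant CpGs: variance tests flag them untestable; the age regression
  reports slope 0 with p = NA.
* All rankings break ties by CpG identifier; all stochastic steps
  (CV folds, partitions, bootstraps, permutations) are driven by explicit
  seeds, so every pipeline stage is bit-reproducible.

## Problem sizes used in the shipped checks

Unit tests run on reduced cohorts (~3,000 CpGs) with the same signal
structure; the end-to-end statistical checks and the reproduction script
use the full default conditions (20,000 CpGs, 75/77 samples) with 25
train/test partitions for the classifier comparison and 1,000 random
instances per brute-force oracle comparison.
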