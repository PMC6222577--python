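# Methods

This package implements a biomarker-prioritization analysis for heart
failure built on a mouse strain panel: transcripts that respond strongly to
a cardiac stressor *and* track a quantitative remodeling trait across
strains are nominated as candidates, checked for directional agreement in a
human failing-vs-non-failing heart comparison, and finally validated as a
plasma analyte in a case-control cohort with logistic regression.  All
stages run on synthetic data with known ground truth; the printed top-DE and
top-correlation tables of the source study ship as fixtures so the overlay
step's worked example is exactly reproducible.

## Differential expression

For each probe the treated-vs-control comparison gives the log2 fold change
(logFC, treated minus control arm means), the mean log2 intensity over all
arrays (AveExpr), and a pooled residual variance `s2_g` on `d_g = n1+n0-2`
degrees of freedom.  Per-probe variances are moderated by an empirical-Bayes
scaled inverse-chi-square prior: the posterior variance is
`s2_post = (d0*s02 + d_g*s2_g)/(d0 + d_g)` and the moderated t is referred
to `d0 + d_g` degrees of freedom.  The hyperparameters `(d0, s02)` are
estimated by closed-form moment matching of `log s2_g` against its
theoretical digamma/trigamma moments (the trigamma equation is inverted by
Newton iteration).  Two limits are exact and tested: `d0 = 0` reproduces the
ordinary pooled t-test to 1e-12, and when the observed spread of the log
variances does not exceed its pure sampling expectation the moment equation
has no finite solution and the estimate is `d0 = inf` — full shrinkage to
`s02`, with a normal reference distribution.  (On the synthetic panel, whose
generating noise SD is common to all probes, `d0 = inf` is therefore the
*correct* answer and is what the estimator returns.)  The implementation is
checked against frozen reference values computed with Bioconductor limma
3.58.1 (eBayes) on a seeded fixture: `d0`, `s02`, and per-probe t and p
agree to at least 6 significant figures.

Multiple testing uses the Benjamini–Hochberg step-up procedure (the printed
table names only an "adjusted p-value"; BH is the GEO2R/limma default) with
both raw and adjusted p reported.  The "top table" is ordered by |logFC|
descending — the printed table's convention — with p-based ordering
available.

## Transcript–trait correlation

Expression is collapsed to strain means within the endpoint (treated) arm,
then each probe is correlated with the per-strain trait change (ΔLVIDd,
mm).  Pearson p-values use the exact transform
`t = r*sqrt((n-2)/(1-r^2))` on `n-2` df; Spearman is Pearson on midranks.
The join on strain is pairwise-complete with no imputation; zero-variance
probes are reported as r = 0, p = 1 with a flag rather than NaN.

The published correlation table prints r and p but not n.  Scanning the
integer n that makes the t-transform reproduce all 47 printed (r, p) pairs
identifies n = 88 uniquely (max |log10 p| discrepancy 0.015, i.e. within
printed rounding), consistent with a 91-strain panel minus a few strains —
so the parametric transform, not a permutation test, is what generated the
printed pairs.  `infer_panel_size` implements this scan and the test suite
pins the inference.

## Overlay nomination and cross-species concordance

Candidate nomination is deliberate set intersection at the symbol level:
probes collapse to symbols keeping the extreme statistic (mean collapse
available), lists are thresholded — defaults |logFC| >= 1.0 with BH p < 0.05
for DE, p < 1e-3 for correlation, which exactly reproduce the printed
tables' contents — and intersected.  Symbols on the known-marker list
(default {Nppb, Timp1, Lgals3, Spp1}, the established HF markers discussed
alongside the candidates) are flagged `novel = False` but never removed.

Mouse symbols map to human by capitalization (Gpnmb → GPNMB), overridable
per symbol by an ortholog table for genuinely different names (Dtr →
HBEGF).  Each candidate is classified against the human DE table as
`concordant` (human p < alpha, same fold-change sign), `discordant`
(significant, opposite sign), `not_significant` (present, p >= alpha), or
`absent`.  The fourth status makes the partition exhaustive — the NPPB case
(p = 0.32 in the human comparison) belongs to it.  Whether the human p
column is raw or adjusted is the caller's decision; alpha defaults to 0.05.

## Cohort validation statistics

Two-sample t-tests exist in raw and summary-statistic forms sharing one set
of formulas (pooled by default — it reproduces the reported mouse plasma
p-values 0.007 and 0.13 under equal-n assumptions; Welch always available,
and the equal-n assumption for the chronic-stimulation control arm is
labeled as such in the tests).  Fisher's exact test uses the probability-
mass two-sided rule (sum of hypergeometric probabilities no larger than the
observed table's), with the doubled-one-sided variant by flag; the reported
odds ratio is the sample cross-product ratio.  Spearman is midrank Pearson
with the t transform.

Logistic regression is Newton/IRLS on the Bernoulli log-likelihood with
step-halving (the log-likelihood trace is recorded and non-decreasing),
convergence declared when the maximum absolute score drops below 1e-8
(at most 50 iterations), standard errors from the inverse observed
information, and Wald 95% intervals `exp(beta ± 1.959964*se)`.  Quasi-
complete separation — diverging coefficients or a broadly saturated linear
predictor (more than 20% of observations with |eta| > 20; a strong but
proper fit saturates at most a small tail) — is warned about and flagged
non-converged rather than silently reported.  The full cohort analysis
mirrors the published layout: baseline comparisons (t-test / Fisher),
univariate logistic per variable, a multivariate model with the fixed
covariate set (age, BMI, hypertension, diabetes, eGFR, LDL-C), an age-only
sensitivity model, and the biomarker-vs-proBNP Spearman correlation when a
proBNP column with at least three complete pairs exists.  The biomarker
enters on the scale named in the config (raw ng/mL default, natural-log
available) and the scale used is recorded in the report.

## Synthetic data

**Strain panel.**  Defaults are the emulated study's design: 91 strains,
both arms per strain, 2 replicates per arm (replicate count is not stated
in the source study; 2 is this package's free choice), 300 probes, log2
baseline N(7, 1.5) (matching the printed AveExpr range), i.i.d. Gaussian
noise with SD 0.5 on the log2 scale, and no strain random effect by default
(no variance components are published; a `strain_effect_sd` knob exists).
Twenty probes carry planted fold changes drawn from |logFC| in [1.0, 2.0] —
the printed top-table's range — with a 25% down-regulated minority, and one
symbol deliberately owns two probes with a shared effect (the duplicate-
probe pattern visible in the printed table).  The trait is
`intercept + sum_j w_j * m_sj + N(0, sigma_eps)` over the *realized*
treated-arm strain means of five trait probes with equal-magnitude,
alternating-sign weights; `sigma_eps` is derived so the per-probe population
correlation hits the target (default 0.37, mid-range of the printed
correlation table): `sigma_eps^2 = w^2*var_m*(1/r^2 - K)`, which also gives
the feasibility constraint `K*r^2 < 1`.  Two probes are planted in both
sets — the ground-truth overlay candidates.

A power note: at the study-realistic default (|r| ≈ 0.37, n = 91, trait
cutoff p < 1e-3) each planted trait probe clears the cutoff only ~60% of
the time, so the intersection misses an overlap gene in a sizable fraction
of draws — visible in the analysis scripts.  Recovery-*rate* checks
(>= 95% of repeats) therefore use a configured clearly-detectable scenario
chosen by a priori power analysis: planted |logFC| in [1.3, 2.0] against an
estimate SE of ~0.05, and trait correlations near 0.55 against a detection
cutoff of ~0.34 (per-gene miss probability below 1%).

**Case-control cohort.**  119 cases and 270 controls with labels fixed
first (ascertainment), biomarker and covariates drawn per group.  Case
distributions are exponential tilts of control distributions
(`f_case ∝ exp(beta*x) * f_control`), which makes the draw *exactly*
consistent with a prospective logistic model with the planted coefficients:
a Gaussian covariate shifts its mean by `beta*sigma^2`, a Bernoulli
covariate multiplies its odds by `exp(beta)`, and the lognormal biomarker is
tilted on the log scale.  This is what makes the OR-recovery and Wald-CI
coverage checks well-posed.  Consequences worth knowing: the planted
biomarker coefficient is per log-ng/mL, and both groups share the control
group's log-scale SD — the control summary (1.20 ± 0.26 ng/mL) and the case
*mean* (0.74) are matched exactly in population, but the case SD is not an
independent dial.  Covariate control-group distributions (age 58 ± 7, BMI
27 ± 4, eGFR 90 ± 15, LDL-C 140 ± 35, hypertension 25%, diabetes 6%) and
planted odds ratios follow the directions of the published logistic table,
with magnitudes chosen once as clinically plausible.  proBNP is generated
for 42 case subjects, independent of the biomarker.  One global seed is
split deterministically (`SeedSequence.spawn`) between panel and cohort
sub-generators; fixed seed means byte-identical output files.

**What the generator does not emulate:** probe cross-hybridization, batch
and normalization artifacts, strain-level genetic correlation (kinship),
heavier-tailed expression noise, covariate-covariate dependence within
groups, and case/control variance heterogeneity.  Passing tests therefore
demonstrate the *statistical machinery* is correct and calibrated under the
stated model, not that the thresholds would have identical operating
characteristics on real arrays.

## Numerical choices and degenerate inputs

- Trigamma inversion: Newton with asymptotic endpoints (y > 1e7, y < 1e-6);
  relative tolerance 1e-10.
- Zero residual variances are excluded from prior estimation with a
  warning; all-zero variances raise a degenerate-data error.
- BH uses a stable mergesort and reverse cumulative minimum; ties in the
  DE table ordering break by p then probe id, so output order is fully
  deterministic.
- Fisher's probability-mass rule tolerates floating-point ties with a
  (1 + 1e-7)-style relative slack, as standard implementations do.
- Logistic CIs use the normal quantile 1.959964; fits with a singular
  information matrix return NaN SEs rather than failing.
- t-tests: both group variances zero with equal means is an error; with
  unequal means the p-value is exactly 0 (infinite t), a documented limit.

## Known limitations

- The moderated-t module fits only the two-group design (no multi-factor
  linear models, array weights, or duplicate-correlation blocking).
- Ortholog mapping is by symbol only; no real homology inference.
- The pipeline's correlation stage uses the treated arm's endpoint means;
  correlating the within-strain response difference is not implemented.
- Printed-table reproduction of the human cohort's odds ratios (0.865 per
  reported unit) is not attempted from synthetic data: the published
  biomarker unit convention for that model is not recoverable from the
  summary statistics, so the package reports per-SD odds ratios for its own
  synthetic cohort instead.
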