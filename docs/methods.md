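# Methods

This note documents the models, defaults and numerical choices behind
`bastage`, and what the synthetic cohorts do and do not emulate.

## Histology scoring

Inflammation grade and fibrosis stage are ordinal 0–3 pathologist scores
supplied as inputs; the package never infers them from images. The
differential score is signed (inflammation minus fibrosis): positive
differentials at or above the threshold mark inflammation-predominant
biopsies, negative ones fibrosis-predominant. The threshold is 2 by
default (the seed-set definition); 1 is supported for the
sensitivity analysis in which weakly predominant biopsies are grouped
directly by histology. Raising the threshold can only shrink the two
predominant groups (monotonicity), and every biopsy receives exactly one
of the three labels.

## Signature derivation

The expression input is a normalized log2 probe × sample matrix
(e.g. RMA output); raw-array processing is out of scope.
Choices that the derivation chain fixes:

- **Median normalization** is a per-probe subtraction on the log2 scale
  (division on the linear scale). It is idempotent and does not change
  between-group mean differences; it standardizes the location of each
  probe before fold-change screening.
- **Fold change** is computed from log2 group means, FC = 2^|Δmean|,
  with a *strict* inequality at the threshold: |Δmean| = 1.0 exactly is
  excluded at the default FC > 2.
- **Welch's t** uses unbiased variances and Welch–Satterthwaite degrees
  of freedom; p-values are two-sided. Probes whose both groups have zero
  variance are excluded from testing with a logged warning (a zero
  variance with unequal means would otherwise produce an infinite
  statistic).
- **BH-FDR** is applied to the fold-change survivors only — the chain
  filters first, then tests — and retention is strict (q < 0.05).
  The raw-p cutoff (0.05) is subsumed by the FDR step at the defaults.

## Nearest-shrunken-centroid classifier

The classifier follows the standard PAM formulation: pooled per-probe
within-class variance s²ᵢ with n − K denominator, a guard offset
s₀ = median(sᵢ), standardized contrasts dᵢₖ with
mₖ = √(1/nₖ + 1/n) (the variance-exact √(1/nₖ − 1/n) variant is a
config switch — scikit-learn's `NearestCentroid` uses it, which the
test suite exploits as a cross-check), soft-thresholding of dᵢₖ, and a
discriminant with a −2 log πₖ prior term. Priors default to empirical
class proportions; a uniform option exists. Class probabilities are
computed after subtracting the minimal discriminant for numerical
stability. Exact discriminant ties are broken by fixed class order with
a logged warning.

The shrinkage threshold Δ is selected once on the seed set by
stratified k-fold cross-validation over a grid containing 0, choosing
the *largest* Δ achieving the minimum error (sparser models win ties).
The repeated-CV voting then runs at that fixed Δ; per-fold re-tuning is
a known alternative and was deliberately not used — a fixed Δ keeps the
100 inner models comparable and the vote interpretable.

### Fold construction and voting

Folds are stratified by dealing each class's shuffled samples
round-robin across folds, so even one-to-two-sample folds stay as
class-balanced as arithmetic allows. Sample order is canonicalized
(sorted IDs) before shuffling, making assignments invariant to input
ordering. Each of the 10 repetitions draws a fresh partition from an
independent child of the run seed.

Labelled samples receive one out-of-fold vote per repetition. For
unlabelled (external) samples the mapping onto the 100 inner models is
underdetermined in the description of the original scheme; the default
here gives each external sample, per repetition, the majority
prediction of that repetition's ten fold models (a tied fold majority
abstains and is recorded). A `full_model` alternative refits one model
per repetition on all labelled samples. Final assignment requires at
least 6 of 10 repetition votes; a 5–5 split — or any pattern in which
no class reaches the bar — leaves the sample unclassified.

## Clinical association

All p-values are two-sided. Fisher's exact test, the conditional-exact
odds-ratio interval (inverting the noncentral hypergeometric
likelihood; the Woolf interval with Haldane's +0.5 correction is the
alternative), Kruskal–Wallis, Kaplan–Meier and the log-rank test are
delegated to scipy, statsmodels and lifelines; the test suite pins each
of them to enumeration or hand-walked oracles on small fixtures.

The Wilcoxon rank-sum test is computed by exhaustive enumeration of
rank assignments whenever n₁ + n₂ ≤ 12 — the enumeration uses midranks
and therefore remains exact under ties — and otherwise by the normal
approximation with tie-corrected variance and an optional 0.5
continuity correction. Age-center comparison defaults to this Wilcoxon
test (the kernel density estimate is descriptive); a seeded permutation
test on the difference of medians is available.

Kernel densities use Gaussian kernels with Silverman's bandwidth
0.9·min(sd, IQR/1.34)·n^(−1/5), evaluated on a grid spanning the data
± 4 bandwidths (integral 1 within 10⁻³).

Survival convention: subjects censored at an event time remain at risk
for those events. A cohort with no events yields a log-rank p of 1 with
a warning rather than an error. The hazard-ratio estimate exposed for
calibration is the Pike O/E estimator from the log-rank risk-set walk
(Cox modelling is intentionally out of scope). Logistic models are fit
by Newton/IRLS maximum likelihood (≤ 50 iterations); complete
separation is detected and flagged in the result instead of raised, and
rank-deficient designs fail naming the offending column.

## Synthetic cohorts

The generator's defaults emulate the target study design: 47 infants; a
14-biopsy histology seed subset (configurably 9 inflammation vs 5
fibrosis); 150 planted signature probes among 2,000; mean |log2 fold
change| 1.5 with ~2/3 of planted probes up in inflammation (77/115);
per-probe Gaussian log2 noise (SD 0.4); group age means 55 vs 71 days
(SD 12, truncated to 30–180); and exponential transplant/death times
with a threefold fibrosis-vs-inflammation hazard ratio, administratively
censored at 24 months.

Decisions worth knowing:

- **Background scale.** Probe means are drawn from N(7, 1.5) on the
  log2 scale, mimicking typical microarray ranges. The default 2,000
  probes is a desk-scale background; the planted-signature geometry
  (and hence recovery behaviour) does not depend on the background
  size, only the multiple-testing burden does.
- **Within-group noise.** The study does not report within-group
  expression variance; the 0.4 log2 SD default is a microarray
  convention, and recovery results should be read relative to it.
- **Histology seed concordance.** At the stringent |differential| ≥ 2
  threshold the predominant histology is taken to define the molecular
  seed groups, so the concordance default is 1.0; lowering it plants
  label noise in the seed set (0.5 gives the calibration null). Seed
  scores are built constructively — the requested seed fraction holds
  exactly, not in expectation.
- **Mixed biopsies are weakly informative.** Among non-seed biopsies,
  17/33 receive a ±1 differential whose sign points to the latent group
  with probability 0.76 (the remainder are zero-differential), so
  threshold-1 histology grouping is noisier than the molecular
  assignment but not useless — mirroring the observed behaviour of
  weakly predominant histology.
- **Outcome rates.** The baseline (inflammation-group) event rate is
  0.02/month: 38% two-year transplant/death in the inflammation group
  and 76% in the fibrosis group at the default hazard ratio, a
  cohort-wide ~60% consistent with historical biliary atresia series.
  Censoring is administrative at 24 months only — no random dropout.
- **Not emulated:** batch effects, probe-level correlation structure,
  missing data, competing risks, and any probe-to-gene annotation.
  Passing recovery tests therefore demonstrate the statistical
  machinery under the assumed model, not robustness to those real-data
  complications.

## Problem sizes in the test and acceptance runs

The test suite and the acceptance script run the full workflow on
2,000-probe, 47-sample cohorts (20 generator seeds for recovery, 50 for
null calibration, 100 for the survival operating characteristics) —
sizes chosen so that a complete run of everything stays in the
low-minute range while keeping the per-cohort seed-set geometry
(9 vs 5 vs 33) identical to the target design.
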