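# Methods

## The modelling problem

Each patient in a biopsy-naive cohort carries an ordered biopsy outcome
(stratum): no evidence of cancer (NEC, never biopsied), negative biopsy
after a raised PSA, or Gleason 3+3, 3+4, 4+3, ≥ 4+4.  Three binary
endpoints derive from it — any cancer, Gs ≥ 3+4 (clinically
significant), Gs ≥ 4+3 (high grade) — and model training uses a
continuous encoding y ∈ {0, 0.5, 1}: 0 for either no-cancer subtype,
0.5 for Gleason 3+3 and 3+4, 1 for dominant pattern 4 or worse.  The
continuous target reflects that two patients with the same biopsy
Gleason score do not share the same tumour burden; the original ordinal
categories are used for everything evaluative.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions
under which every downstream claim is verified.

**Peptides** (CE-MS): value = Bernoulli(detection rate) ×
LogNormal(μ_f + δ_fs, σ).  The default detection rate is 0.6 for all
peptides and all strata; σ (`noise_sd`, natural-log scale) defaults
to 1.0.  Baseline log-medians μ_f are drawn uniformly on
[ln 50, ln 2000] arbitrary intensity units.  Non-detections are exact
zeros, as in instrument exports.

**EV-RNA**: counts = 2^N(μ_f + δ'_fs, σ) × lane_s, with μ_f uniform on
log2 [8, 1024] counts, σ = `noise_sd` in log2 units, and a per-sample
lane efficiency lane_s = 2^N(0, 0.25) that multiplies all probes
including a six-point positive-control ladder (expected counts
4096 … 4).  Positive-control normalisation (per-sample factor = grand
mean of control geometric means / sample's control geometric mean)
removes the lane effect exactly in expectation; controls are dropped
after normalisation, leaving the 167 endogenous probes.

**Planted effects.**  Each informative feature has a target linear fold
change F (cancer vs no-cancer, on the detected-value scale; defaults
are the study's reported table: 14 peptides from 7.1× down to 0.5×,
6 probes from 4.8× to 0.8×).  Effects grow with stratum ordinality via
fixed gradient weights g = (0.70, 0.90, 1.10, 1.25) for (3+3, 3+4,
4+3, ≥ 4+4); a per-feature scalar c solves Σ_s w_s·F^(c·g_s) = F with
w_s the cancer-stratum shares, so the *all-cancer* vs no-cancer
contrast equals F exactly while the continuous outcome remains
learnable.  The multiplicative shift applies to the log-mean with equal
variance in both groups, so the ratio of expected detected values is
exact, not approximate.

**Clinical variables.**  Age ~ Normal and PSA ~ log-normal per group,
calibrated to the development-cohort summaries (no-cancer: age
66.2 ± 8.3, PSA median 5.3, IQR 2.3–7.9; cancer: 70.2 ± 7.8, median
10.4, IQR 6.9–16.6; log-sd matched to the IQR).  DRE size is
categorical with the per-group frequencies of the cohort table;
urine volume is an uninformative nuisance (Normal(35, 15) mL,
truncated at 5).  The paper reports no within-stratum variance for any
omics feature, so all variance parameters above are assumptions of this
package, chosen once at plausible instrument-scale values; planted
fold changes, group sizes and clinical summaries are the reported ones.

**What the generator does not emulate:** inter-feature correlation
(features are independent given stratum), batch effects beyond the
single lane factor, detection probability varying with abundance or
disease, heavy-tailed outliers, and missing clinical data.  Passing
tests therefore demonstrate correctness of the machinery under the
assumed generative model, not clinical performance on real cohorts.

**Seeds.**  One master seed; child generators use fixed documented
offsets (clinical 0, peptide 1, EV-RNA 2 as `default_rng([seed, k])`).
Output is bit-identical under a fixed seed.

## Preprocessing

The detection filter keeps a peptide iff detected in ≥ 30% of cancer
samples or ≥ 30% of non-cancer samples, inclusive ("at least 30%"),
with cancer defined as any Gleason-positive stratum.  It is idempotent
and never retains an all-zero column.  Both quantitative blocks use
log2(x + 1), which maps non-detections to exactly zero; any monotone
variant could be substituted via the `offset` argument of the
normaliser.  DRE size enters the design as a single ordinal column
(Unknown = 0, Small = 1, Medium = 2, Large = 3): the clinical block
contributes exactly four predictors, making the integrated design
4 + 643 + 167 = 814 columns, and Unknown stays an explicit level
rather than being imputed.

## Feature selection

A squared-error LASSO on the continuous outcome, 20-fold
cross-validated on one shared, balanced, seeded fold assignment reused
by all four model variants.  Predictors are standardised internally
(the blocks mix years, ng/mL and log2 counts) and coefficients are
mapped back to the original scale; the penalty is the CV-minimum on a
100-point log-spaced path (not the one-standard-error rule).  A
constant outcome yields an empty selection; zero-variance columns are
tolerated and never selected.  Whether selection should use the
continuous encoding or a binary endpoint was genuinely open; the
continuous choice keeps selection and training targets identical.

## Risk models

Regression forests with 401 trees, per-tree subsample 0.632·n drawn
without replacement, one third of features tried per split, minimum
leaf size 5 — the classic regression-forest defaults with bootstrap
replaced by subsampling.  The 0.632 fraction is the expected unique
fraction of a with-replacement bootstrap, the convention when
resampling without replacement; it is configurable.  Per-tree
subsamples are chosen by ranking a keyed hash of (seed, tree, patient
id), which makes the index sets deterministic, identical across model
variants fitted on the same cohort, and equivariant under row
permutation (the subsample follows the patient).  At these defaults a
patient is in-sample for any given tree with probability 0.632, so the
chance of having no out-of-bag tree is 0.632^401 ≈ 10^-80; the OOB
score (mean over trees excluding the patient) is always defined.
Scores are used as-is, without recalibration; they live in [0, 1]
because leaf means of y ∈ [0, 1] do.

If LASSO selects nothing for a variant, the pipeline proceeds with an
intercept-only comparator predicting the mean outcome and warns, so a
run never aborts on a weak block.

**Known limitation — selection optimism.**  Feature selection sees the
full cohort; only the forest is internally cross-validated by OOB
aggregation.  On null data a variant whose LASSO selection captured
chance correlations can show OOB AUC noticeably above 0.5 (we have
measured up to ≈ 0.63 on pure noise).  This mirrors the study design
being reproduced and is why the null-data test asserts no *genuine*
discrimination (mean across models at chance) rather than a strict
binomial band per model.

## Evaluation

AUC is the Mann–Whitney concordance probability with ties counted ½
(midrank formula; verified against exhaustive pairwise comparison).
Confidence intervals are percentile intervals from 1000 stratified
bootstrap resamples — positives and negatives resampled separately —
and model comparisons are paired one-sided bootstrap tests sharing the
resample indices, with p = (1 + #{Δ ≤ 0})/(B + 1) so p is never 0.
The ordinal association is a cumulative-logit proportional-odds model
(maximum likelihood, BFGS) of the merged five-level outcome
(NC < 3+3 < 3+4 < 4+3 < ≥ 4+4) on the risk score, reported as
exp(0.1·β) with a Wald CI.  Group mean differences use the BCa
bootstrap (bias correction from the proportion of resamples below the
point estimate, acceleration from jackknife skewness).  BCa is
reserved for mean differences and percentile intervals for AUC,
matching the distinct conventions of the tools each statistic
originates from.

## Decision-curve analysis

The decision rule is score ≥ t (ties biopsy).  Thresholds default to
0.05–0.50 in steps of 0.01.  Because the development cohort is
cancer-enriched, each of 1000 resamples redraws 197 patients with
replacement, stratified to the CAP control-arm proportions
(60.6 / 23.6 / 8.7 / 7.1%); stratum counts are the largest-remainder
rounding of proportion × 197 (119 / 47 / 17 / 14), exact in every
draw.  The GS7 target stratum pools Gleason 3+4 and 4+3 (the trial
reports Gleason sums); the resample size 197 is a fixed configurable
constant.  Endpoint prevalence is recomputed inside each resample and
used to standardize that resample's net benefit, and curves report the
across-resample mean sNB per model, alongside a treat-all policy
(biopsy iff PSA ≥ 4 ng/mL) and treat-none (sNB ≡ 0).  Biopsy net
reduction uses the un-standardized mean NB of a model minus the
standard-of-care model, times (1 − t)/t, per 100 patients.

## Numerical choices and degenerate inputs

Ties in the largest-remainder promotion break by stratum order (NC,
GS6, GS7, GS8+).  Bootstrap quantiles use the default linear
interpolation; degenerate bootstrap distributions (e.g. perfectly
separated scores) collapse the interval to the point.  The ordinal fit
raises with diagnostics on non-convergence rather than returning a
silent estimate.  Cohort TSVs round-trip losslessly (`%.17g` output,
round-trip float parsing on input).

## Problem sizes in the test suite

Tests that fit the full four-variant pipeline repeatedly use reduced
omics blocks (40 peptides, 20 probes) with the default 192-patient
group structure; the structural checks (814 columns, filter counts)
use the full 643/167 defaults.  Replicate counts follow the stated
study conditions: 100 seeds for selection recovery, 100 for ordinal
recovery, 200 for each interval-coverage study, 50 for the
integration-gain property, 1000 resamples for prevalence matching.
The integration-gain cohorts plant complementary signals split across
blocks (4 peptides and 3 probes at fold 2.0 plus the default clinical
age/PSA effects), chosen in a pre-freeze design study so that each
single-omics model is informative but clearly below the integrated
model's reach.
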