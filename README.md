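# exospec

Multi-omics urinary risk models for clinically significant prostate
cancer, built as a reusable, fully tested Python pipeline.

Men with a raised PSA face an invasive prostate biopsy even though a
large fraction turn out to have no cancer or indolent disease.  Urine
carries prostatic secretions — excreted peptides measurable by CE-MS
and extracellular-vesicle RNA (EV-RNA) measurable by hybridisation
probe panels — and combining these with clinical variables can predict
the biopsy outcome well enough to let many men skip the needle.  This
package implements that analysis end to end:

1. **Synthetic cohorts** (`exospec.synthetic`) — a generator that
   emulates a development cohort of 192 men (59 no-cancer, 31 Gleason
   3+3, 48 Gs 3+4, 25 Gs 4+3, 29 Gs ≥ 4+4) with 643 zero-inflated
   peptide intensities, 167 EV-RNA probes plus positive controls, and
   clinical variables, with informative features planted at known
   linear fold changes so every downstream stage can be validated
   against ground truth.
2. **Preprocessing** (`exospec.preprocess`) — a-priori peptide
   filtering (keep a peptide iff detected in ≥ 30% of cancer *or* of
   non-cancer samples), positive-control geometric-mean normalisation
   of probe counts, log2 transforms, and per-model design matrices.
   The integrated design has 814 predictors (4 clinical + 643 peptide
   + 167 probe).
3. **Feature selection** (`exospec.feature_selection`) — 20-fold
   cross-validated LASSO on the continuous Gleason outcome; only
   variables with non-zero coefficients at the CV-minimum penalty
   survive.  All model variants share one fold assignment.
4. **Risk models** (`exospec.risk_models`) — the outcome is encoded
   0 (no cancer) / 0.5 (Gs 3+3, 3+4) / 1 (Gs ≥ 4+3) and four
   comparator regression forests are trained (401 trees, per-tree
   subsamples of 0.632·n drawn *without replacement*, identical index
   sets across variants): `SoC` (clinical only), `MassSpec` (peptides),
   `ExoRNA` (probes) and the integrated `ExoSpec`.  Risk scores are
   out-of-bag (OOB) predictions — each patient is scored only by trees
   that never saw them.
5. **Evaluation** (`exospec.evaluation`) — Mann–Whitney AUC with
   1000-resample stratified-bootstrap percentile CIs, paired one-sided
   bootstrap model comparisons, a cumulative-logit proportional-odds
   odds ratio per 0.1 score, and BCa bootstrap mean-difference
   intervals for estimation plots.
6. **Decision-curve analysis** (`exospec.decision_analysis`) — net
   benefit NB(t) = TP/n − (FP/n)·t/(1−t), standardized net benefit
   sNB = NB/prevalence, averaged over 1000 stratified bootstrap
   resamples (size 197) matched to the CAP-trial control-arm Gleason
   distribution (60.6% no cancer / 23.6% GS6 / 8.7% GS7 / 7.1% GS ≥ 8),
   a PSA ≥ 4 ng/mL treat-all policy, and the net biopsy reduction vs
   the standard of care, (NB_model − NB_SoC)·(1−t)/t per 100 patients.

## Worked example

`examples/` contains one short script per capability.  From
`examples/04_decision_curves.py` (seeded, so reproducible):

```
mean standardized net benefit (significant disease, Gs >= 3+4):
threshold        SoC   MassSpec     ExoRNA    ExoSpec  treat_all
   0.10        0.434      0.470      0.585      0.549      0.506
   0.20       -0.160      0.108      0.212      0.302     -0.053
   0.25       -0.461     -0.062      0.149      0.199     -0.388
   0.30       -0.642     -0.063      0.052      0.210     -0.771

net biopsy reduction vs SoC, per 100 patients:
   t=0.10:  16.3
   t=0.20:  29.1
   t=0.25:  31.2
   t=0.30:  31.3
```

Reading: at an accepted risk threshold of 0.25 the integrated model
retains a positive standardized net benefit on a screening-prevalence
population while the clinical standard of care and the biopsy-everyone
policy are net harmful, and using it instead of the clinical model
would avoid about 31 unnecessary biopsies per 100 men.  The companion
scripts print the cohort structure (`01`), the selected features per
model (`02` — the clinical model keeps exactly age and PSA) and AUCs
with bootstrap CIs plus the proportional-odds ratio (`03`).

A full reproducible run (cohort TSVs, selection report, risk scores,
evaluation JSON, decision-curve TSVs and a hashed manifest) is:

```sh
exospec run-all --seed 1 --outdir runs/demo
```

or stage by stage (`exospec simulate|preprocess|select|train|evaluate|dca`).

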