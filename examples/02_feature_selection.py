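"""Preprocess the cohort and run cross-validated LASSO selection.

Peptides are filtered to those detected in at least 30% of cancer or
non-cancer samples, EV-RNA counts are normalised against the positive
controls and both blocks are log2 transformed.  A 20-fold
cross-validated LASSO then picks the variables associated with the
continuous Gleason outcome for each comparator model.
"""

import numpy as np

import exospec as xs

spec = xs.default_spec(seed=1)
patients, clinical, peptide, evrna = xs.generate_cohort(spec)
blocks = xs.preprocess_cohort(
    patients, {"clinical": clinical, "peptide": peptide, "evrna": evrna}
)
print(f"peptides after detection filter: {blocks['peptide'].n_features}")
print(f"probes after normalisation: {blocks['evrna'].n_features}")

design = xs.assemble_design(blocks["clinical"], blocks["peptide"], blocks["evrna"], "ExoSpec")
print(f"integrated design matrix: {design.n_columns} predictors "
      "(4 clinical + 643 peptides + 167 probes)")

y = np.array([xs.encode_outcome(s) for s in patients["stratum"]])
folds = xs.assign_folds(len(y), k=20, seed=2)
truth = set(xs.planted_truth(spec)["peptide"]) | set(xs.planted_truth(spec)["evrna"])
for variant in ("SoC", "MassSpec", "ExoRNA", "ExoSpec"):
    dm = xs.assemble_design(blocks["clinical"], blocks["peptide"], blocks["evrna"], variant)
    sel = xs.cv_lasso_select(dm, y, folds)
    hits = sorted(set(sel.names) & truth)
    print(f"{variant}: {len(sel.names)} selected, planted-truth hits: {hits}")
# SoC should retain age and PSA; the omics variants should recover a
# majority of their blocks' planted features plus some noise columns.
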