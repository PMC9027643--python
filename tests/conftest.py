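import numpy as np
import pytest

import exospec as xs


@pytest.fixture(scope="session")
def default_cohort():
    """The study-default synthetic cohort: 192 patients, 643 peptides,
    167 probes (+ positive controls)."""
    spec = xs.default_spec(seed=42)
    patients, clin, pep, rna = xs.generate_cohort(spec)
    return spec, patients, {"clinical": clin, "peptide": pep, "evrna": rna}


@pytest.fixture(scope="session")
def small_spec():
    """A reduced cohort (40 peptides, 20 probes) that keeps the default
    group sizes and planted-effect structure but fits fast."""
    effects = tuple(e for e in xs.synthetic.DEFAULT_EFFECTS)
    return xs.default_spec(seed=7, n_peptides=40, n_evrna=20, effect_table=effects)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    patients, clin, pep, rna = xs.generate_cohort(small_spec)
    return patients, {"clinical": clin, "peptide": pep, "evrna": rna}


@pytest.fixture(scope="session")
def small_comparators(small_cohort):
    """Comparator models fitted once on the reduced cohort."""
    patients, blocks = small_cohort
    res = xs.build_comparators(patients, blocks, fold_seed=11, forest_seed=12)
    return patients, res


def random_scores_and_labels(rng, n_max=12):
    """A random tiny scored cohort guaranteed to contain both classes."""
    n = int(rng.integers(3, n_max + 1))
    scores = np.round(rng.random(n), 2)  # rounding forces occasional ties
    labels = rng.random(n) < 0.5
    if labels.all():
        labels[int(rng.integers(0, n))] = False
    if not labels.any():
        labels[int(rng.integers(0, n))] = True
    return scores, labels
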