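"""Outcome encoding, without-replacement forests and OOB risk scores."""

import numpy as np
import pytest

import exospec as xs
from exospec.risk_models import EmptySelectionError, train_forest, oob_scores
from exospec.strata import GleasonStratum as G


def test_outcome_encoding_matches_gleason_mapping():
    assert xs.encode_outcome(G.NEC) == 0.0
    assert xs.encode_outcome(G.NEG_BIOPSY) == 0.0
    assert xs.encode_outcome(G.GS3_3) == 0.5
    assert xs.encode_outcome(G.GS3_4) == 0.5
    assert xs.encode_outcome(G.GS4_3) == 1.0
    assert xs.encode_outcome(G.GS4PLUS) == 1.0


def _fit(X, y, seed=0, **kw):
    n = len(y)
    ids = [f"P{i:03d}" for i in range(n)]
    names = [f"x{j}" for j in range(X.shape[1])]
    return train_forest(X, y, ids, names, seed=seed, **kw)


class TestForest:
    def test_constant_outcome_predicts_constant(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="constant outcome"):
            model = _fit(rng.normal(size=(40, 3)), np.full(40, 0.5), n_trees=25)
        scores = oob_scores(model)
        np.testing.assert_allclose(scores.scores, 0.5)
        assert scores.oob

    def test_same_seed_identical_subsamples_and_scores(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        y = rng.choice([0.0, 0.5, 1.0], 50)
        m1 = _fit(X, y, seed=9, n_trees=31)
        m2 = _fit(X, y, seed=9, n_trees=31)
        np.testing.assert_array_equal(m1.in_sample, m2.in_sample)
        np.testing.assert_array_equal(oob_scores(m1).scores, oob_scores(m2).scores)

    def test_subsample_sets_identical_across_variants(self):
        """The per-tree index sets depend only on (seed, tree, patient id),
        not on the feature matrix, so all model variants share them."""
        rng = np.random.default_rng(2)
        y = rng.choice([0.0, 1.0], 60)
        m_a = _fit(rng.normal(size=(60, 3)), y, seed=5, n_trees=20)
        m_b = _fit(rng.normal(size=(60, 11)), y, seed=5, n_trees=20)
        np.testing.assert_array_equal(m_a.in_sample, m_b.in_sample)

    def test_permuting_patients_permutes_scores(self):
        rng = np.random.default_rng(3)
        n = 60
        X = rng.normal(size=(n, 3))
        y = (X[:, 0] > 0).astype(float)
        ids = [f"P{i:03d}" for i in range(n)]
        names = ["a", "b", "c"]
        base = oob_scores(train_forest(X, y, ids, names, n_trees=51, seed=4)).scores
        perm = rng.permutation(n)
        permuted = oob_scores(
            train_forest(X[perm], y[perm], [ids[i] for i in perm], names, n_trees=51, seed=4)
        ).scores
        np.testing.assert_allclose(permuted, base[perm])

    def test_oob_never_uses_own_record(self):
        rng = np.random.default_rng(4)
        model = _fit(rng.normal(size=(30, 2)), rng.choice([0.0, 1.0], 30), n_trees=15)
        for t in range(model.n_trees):
            in_set = set(model.in_sample[t])
            assert len(in_set) == model.in_sample.shape[1]  # without replacement
            assert len(in_set) < model.n_patients  # strict subset
        # every patient is OOB for at least one tree at these defaults
        counts = np.zeros(model.n_patients, int)
        for t in range(model.n_trees):
            counts[model.in_sample[t]] += 1
        assert np.all(counts < model.n_trees)

    def test_separable_binary_feature_oob_near_truth(self):
        x = np.repeat([0.0, 1.0], 50)
        y = x.copy()
        scores = oob_scores(_fit(x[:, None], y, seed=6)).scores
        assert np.all(np.abs(scores - y) < 0.1)

    def test_scores_bounded_and_empty_selection_raises(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 2))
        y = rng.choice([0.0, 0.5, 1.0], 40)
        scores = oob_scores(_fit(X, y, n_trees=25)).scores
        assert np.all((scores >= 0) & (scores <= 1))
        with pytest.raises(EmptySelectionError):
            _fit(np.empty((40, 0)), y)


class TestComparators:
    def test_four_variants_full_length_scores(self, small_comparators):
        patients, res = small_comparators
        assert set(res.scores) == {"SoC", "MassSpec", "ExoRNA", "ExoSpec"}
        for rs in res.scores.values():
            assert len(rs.scores) == len(patients)

    def test_stratum_score_gradient(self, small_comparators):
        """Mean integrated-model score rises with the planted stratum
        gradient: NC < Gleason 3+3/3+4 < Gleason >= 4+3."""
        patients, res = small_comparators
        s = res.scores["ExoSpec"].scores
        strata = list(patients["stratum"])
        nc = s[[not t.any_cancer for t in strata]].mean()
        low = s[[t.any_cancer and not t.ge_4_3 for t in strata]].mean()
        high = s[[t.ge_4_3 for t in strata]].mean()
        assert nc < low < high

    def test_forest_null_features_auc_at_chance(self):
        """A forest given fixed noise features has OOB any-cancer AUC
        within 0.5 +/- 0.1 (binomial tolerance at n = 192)."""
        for seed in range(3):
            spec = xs.null_spec(seed=seed, n_peptides=5, n_evrna=5)
            patients, *_ = xs.generate_cohort(spec)
            strata = list(patients["stratum"])
            y = np.array([xs.encode_outcome(s) for s in strata])
            rng = np.random.default_rng(50 + seed)
            scores = oob_scores(_fit(rng.normal(size=(len(y), 5)), y, seed=seed)).scores
            auc = xs.roc_auc(scores, xs.ENDPOINTS["any_cancer"], strata)
            assert abs(auc - 0.5) < 0.1, (seed, auc)

    def test_null_cohort_no_model_shows_genuine_discrimination(self):
        """With every planted effect removed no comparator discriminates.
        Because LASSO selection sees the full cohort, OOB scores retain a
        mild selection optimism, so individual-model null AUCs can stray
        somewhat above chance; the across-model mean stays at 0.5."""
        import warnings

        aucs = []
        for seed in range(3):
            spec = xs.null_spec(seed=seed, n_peptides=30, n_evrna=15)
            patients, clin, pep, rna = xs.generate_cohort(spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = xs.build_comparators(
                    patients, {"clinical": clin, "peptide": pep, "evrna": rna},
                    fold_seed=100 + seed, forest_seed=200 + seed,
                )
            strata = list(patients["stratum"])
            for variant, rs in res.scores.items():
                auc = xs.roc_auc(rs.scores, xs.ENDPOINTS["any_cancer"], strata)
                assert abs(auc - 0.5) < 0.2, (seed, variant, auc)
                aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05
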