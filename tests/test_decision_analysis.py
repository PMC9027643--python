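"""Net benefit, standardized net benefit, CAP resampling and Eq.-style
biopsy-reduction arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import exospec as xs
from exospec.decision_analysis import cap_stratum_targets, _largest_remainder
from exospec.strata import GleasonStratum as G

ANY = xs.ENDPOINTS["any_cancer"]


class TestNetBenefit:
    def test_hand_worked_example(self):
        # n=100, TP=20, FP=30 at t=0.2 -> NB = 0.20 - 0.30*0.25 = 0.125
        scores = np.concatenate([np.ones(50), np.zeros(50)])
        labels = np.zeros(100, bool)
        labels[:20] = True  # 20 TP among the 50 biopsied
        nb, tp, fp = xs.net_benefit(scores, labels, 0.2)
        assert (tp, fp) == (20, 30)
        assert nb == pytest.approx(0.125)
        assert xs.snb(nb, 0.25) == pytest.approx(0.5)

    def test_perfect_classifier_nb_equals_prevalence(self):
        labels = np.array([True] * 3 + [False] * 7)
        scores = labels.astype(float)
        for t in (0.1, 0.25, 0.5, 0.9):
            nb, _, _ = xs.net_benefit(scores, labels, t)
            assert nb == pytest.approx(0.3)
            assert xs.snb(nb, 0.3) == pytest.approx(1.0)

    def test_biopsy_nobody_nb_zero(self):
        nb, tp, fp = xs.net_benefit(np.zeros(8), np.ones(8, bool), 0.3)
        assert nb == 0.0 and tp == 0 and fp == 0

    def test_threshold_domain(self):
        for t in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                xs.net_benefit([0.5], [True], t)
        with pytest.raises(ValueError):
            xs.snb(0.1, 0.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_confusion_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        scores = np.round(rng.random(n), 2)
        labels = rng.random(n) < 0.5
        for t in np.arange(0.05, 1.0, 0.05):
            nb, tp, fp = xs.net_benefit(scores, labels, t)
            tp_o = fp_o = 0
            for s, l in zip(scores, labels):
                if s >= t:
                    tp_o, fp_o = tp_o + int(l), fp_o + int(not l)
            assert (tp, fp) == (tp_o, fp_o)
            assert nb == pytest.approx(tp_o / n - (fp_o / n) * t / (1 - t))
            # NB never exceeds prevalence
            assert nb <= labels.mean() + 1e-12


class TestTreatAll:
    def test_boundary_policies(self):
        assert xs.treat_all_nb([5, 6, 7], [True] * 3, 0.3) == pytest.approx(1.0)
        assert xs.treat_all_nb([1, 2, 3], [True] * 3, 0.3) == 0.0

    def test_mixed_toy_hand_count(self):
        psa = np.array([2.0, 3.9, 4.0, 5.0, 8.0, 10.0, 1.0, 4.5, 6.0, 20.0])
        labels = np.array([0, 0, 1, 0, 1, 1, 1, 0, 0, 1], bool)
        # PSA >= 4 biopsies indices 2,3,4,5,7,8,9 -> TP=4, FP=3
        t = 0.25
        expected = 4 / 10 - (3 / 10) * t / (1 - t)
        assert xs.treat_all_nb(psa, labels, t) == pytest.approx(expected)


class TestCapResample:
    def test_largest_remainder_targets(self):
        targets = cap_stratum_targets(xs.CAP_DEFAULT, 197)
        assert targets == {"NC": 119, "GS6": 47, "GS7": 17, "GS8plus": 14}
        assert sum(targets.values()) == 197

    def test_largest_remainder_is_exact_partition(self):
        # 7 * [.5, .25, .25] = [3.5, 1.75, 1.75]; floors give 5, and the two
        # largest remainders (0.75, 0.75) are promoted
        counts = _largest_remainder([0.5, 0.25, 0.25], 7)
        assert counts.tolist() == [3, 2, 2]

    def test_every_draw_hits_exact_targets(self, default_cohort):
        _, patients, _ = default_cohort
        strata = list(patients["stratum"])
        for seed in range(5):
            idx = xs.cap_resample(strata, n_out=197, seed=seed)
            drawn = [strata[i] for i in idx]
            assert len(idx) == 197
            assert sum(not s.any_cancer for s in drawn) == 119
            assert sum(s is G.GS3_3 for s in drawn) == 47
            assert sum(s in (G.GS3_4, G.GS4_3) for s in drawn) == 17
            assert sum(s is G.GS4PLUS for s in drawn) == 14

    def test_missing_stratum_is_error(self):
        with pytest.raises(ValueError, match="GS8plus"):
            xs.cap_resample([G.NEG_BIOPSY, G.GS3_3, G.GS3_4], n_out=20, seed=0)

    def test_deterministic_under_seed(self, default_cohort):
        _, patients, _ = default_cohort
        strata = list(patients["stratum"])
        np.testing.assert_array_equal(
            xs.cap_resample(strata, seed=3), xs.cap_resample(strata, seed=3)
        )


@pytest.fixture(scope="module")
def cohort():
    rng = np.random.default_rng(0)
    strata = (
        [G.NEC] * 10 + [G.NEG_BIOPSY] * 15 + [G.GS3_3] * 12
        + [G.GS3_4] * 15 + [G.GS4_3] * 8 + [G.GS4PLUS] * 10
    )
    labels = ANY.labels(strata)
    scores = np.clip(labels * 0.5 + rng.random(len(strata)) * 0.5, 0, 1)
    psa = rng.uniform(1, 20, len(strata))
    return strata, scores, psa


class TestDecisionCurves:
    def test_identical_models_coincide(self, cohort):
        strata, scores, psa = cohort
        dc = xs.decision_curves(
            {"A": scores, "B": scores.copy()}, strata, psa, ANY, B=25, seed=1
        )
        np.testing.assert_allclose(dc.model_snb["A"], dc.model_snb["B"])
        np.testing.assert_array_equal(dc.treat_none_snb, 0.0)

    def test_perfect_model_snb_one_everywhere(self, cohort):
        strata, _, psa = cohort
        perfect = ANY.labels(strata).astype(float)
        dc = xs.decision_curves({"perfect": perfect}, strata, psa, ANY, B=25, seed=2)
        np.testing.assert_allclose(dc.model_snb["perfect"], 1.0)

    def test_single_resample_matches_hand_computation(self):
        strata = [G.NEG_BIOPSY] * 6 + [G.GS3_3] * 5 + [G.GS3_4] * 5 + [G.GS4PLUS] * 4
        rng = np.random.default_rng(5)
        scores = np.round(rng.random(20), 2)
        psa = np.round(rng.uniform(1, 15, 20), 1)
        grid = np.array([0.2, 0.4])
        dc = xs.decision_curves(
            {"m": scores}, strata, psa, ANY, thresholds=grid, n_out=20, B=1, seed=9
        )
        idx = xs.cap_resample(strata, n_out=20, seed=np.random.default_rng(9))
        labels = ANY.labels([strata[i] for i in idx])
        prev = labels.mean()
        for j, t in enumerate(grid):
            nb, _, _ = xs.net_benefit(scores[idx], labels, t)
            assert dc.model_snb["m"][j] == pytest.approx(nb / prev)
            assert dc.model_nb["m"][j] == pytest.approx(nb)


class TestBiopsyReduction:
    def test_closed_form_identities(self):
        assert xs.biopsy_net_reduction(0.12, 0.12, 0.3) == 0.0
        assert xs.biopsy_net_reduction(0.30, 0.18, 0.5) == pytest.approx(100 * 0.12)
        assert xs.biopsy_net_reduction(0.10, 0.05, 0.25) == pytest.approx(15.0)

    def test_linear_in_delta_and_decreasing_in_threshold(self):
        r1 = xs.biopsy_net_reduction(0.10, 0.05, 0.2)
        r2 = xs.biopsy_net_reduction(0.15, 0.05, 0.2)
        assert r2 == pytest.approx(2 * r1)
        ts = np.linspace(0.1, 0.9, 9)
        reds = [xs.biopsy_net_reduction(0.10, 0.05, t) for t in ts]
        assert np.all(np.diff(reds) < 0)

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            xs.biopsy_net_reduction(0.1, 0.05, 1.0)
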