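"""Peptide filter, transforms, design assembly and cohort I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import exospec as xs
from exospec.preprocess import CohortError
from exospec.strata import GleasonStratum as G


def _pep(values):
    values = np.atleast_2d(np.asarray(values, float))
    names = [f"f{j}" for j in range(values.shape[1])]
    return xs.OmicsBlock("peptide", names, values)


def _strata(n_cancer, n_nc):
    return [G.GS3_4] * n_cancer + [G.NEG_BIOPSY] * n_nc


class TestFilterPeptides:
    def test_all_zero_column_removed(self):
        block = _pep(np.zeros((4, 2)))
        block.values[:, 1] = 1.0
        out = xs.filter_peptides(block, _strata(2, 2))
        assert out.feature_names == ["f1"]

    def test_inclusive_30_percent_boundary(self):
        # 10 cancer / 10 NC; detected in exactly 3 cancer, 0 NC -> retained;
        # detected in 2 and 2 -> removed
        values = np.zeros((20, 2))
        values[:3, 0] = 5.0
        values[[0, 1, 10, 11], 1] = 5.0
        out = xs.filter_peptides(_pep(values), _strata(10, 10))
        assert out.feature_names == ["f0"]

    def test_single_group_cohort_is_error(self):
        with pytest.raises(CohortError, match="cancer"):
            xs.filter_peptides(_pep(np.ones((3, 2))), [G.GS3_4] * 3)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        block = _pep(rng.random((30, 40)) * (rng.random((30, 40)) < 0.4))
        strata = _strata(18, 12)
        once = xs.filter_peptides(block, strata)
        twice = xs.filter_peptides(once, strata)
        assert once.feature_names == twice.feature_names
        np.testing.assert_array_equal(once.values, twice.values)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_recount(self, seed):
        """Retention decisions agree with an explicit per-column recount."""
        rng = np.random.default_rng(seed)
        n_cancer = int(rng.integers(1, 8))
        n_nc = int(rng.integers(1, 8))
        p = int(rng.integers(1, 12))
        values = rng.random((n_cancer + n_nc, p)) * (rng.random((n_cancer + n_nc, p)) < 0.5)
        strata = _strata(n_cancer, n_nc)
        out = xs.filter_peptides(_pep(values), strata)
        kept = set(out.feature_names)
        for j in range(p):
            det_c = sum(values[i, j] > 0 for i in range(n_cancer))
            det_n = sum(values[i, j] > 0 for i in range(n_cancer, n_cancer + n_nc))
            expected = det_c / n_cancer >= 0.30 or det_n / n_nc >= 0.30
            assert (f"f{j}" in kept) == expected
            if det_c + det_n == 0:
                assert f"f{j}" not in kept


class TestLogTransform:
    def test_log2_plus_one_values(self):
        block = _pep([[0.0, 1.0, 7.0]])
        out = xs.log_transform_peptides(block)
        np.testing.assert_allclose(out.values, [[0.0, 1.0, 3.0]])
        assert out.scale == "log2"

    def test_negative_value_rejected(self):
        block = xs.OmicsBlock("evrna", ["a"], [[1.0]])
        with pytest.raises(CohortError):
            xs.log_transform_peptides(block)


class TestNormalizeEvrna:
    def _block(self, values, names=None):
        values = np.asarray(values, float)
        names = names or [f"g{j}" for j in range(values.shape[1])]
        return xs.OmicsBlock("evrna", names, values)

    def test_identical_controls_factors_are_one(self):
        block = self._block(
            [[10.0, 3.0, 8.0], [20.0, 3.0, 8.0]], ["g0", "POS_A", "POS_B"]
        )
        out = xs.normalize_evrna(block, ["POS_A", "POS_B"])
        np.testing.assert_allclose(out.values[:, 0], np.log2([11.0, 21.0]))
        assert out.feature_names == ["g0"]

    def test_two_sample_geometric_mean_scaling(self):
        # sample B's control geometric mean is 2x sample A's, so B's
        # endogenous counts are halved relative to A before log2:
        # factors = mean(gm)/gm = (1.5, 0.75); B: 40*0.75 = 30 vs A: 40*1.5 = 60
        block = self._block(
            [[40.0, 2.0, 8.0], [40.0, 4.0, 16.0]], ["g0", "POS_A", "POS_B"]
        )
        out = xs.normalize_evrna(block, ["POS_A", "POS_B"])
        np.testing.assert_allclose(2 ** out.values[:, 0] - 1, [60.0, 30.0])

    def test_zero_count_maps_to_log2_offset(self):
        block = self._block([[0.0, 4.0]], ["g0", "POS_A"])
        out = xs.normalize_evrna(block, ["POS_A"], offset=1.0)
        assert out.values[0, 0] == 0.0

    def test_all_zero_controls_is_error(self):
        block = self._block([[5.0, 0.0]], ["g0", "POS_A"])
        with pytest.raises(CohortError, match="positive control"):
            xs.normalize_evrna(block, ["POS_A"])


class TestAssembleDesign:
    def test_variant_block_restriction_and_partition(self, default_cohort):
        _, patients, blocks = default_cohort
        proc = xs.preprocess_cohort(patients, blocks)
        widths = {}
        for variant in ("SoC", "MassSpec", "ExoRNA", "ExoSpec"):
            dm = xs.assemble_design(proc["clinical"], proc["peptide"], proc["evrna"], variant)
            widths[variant] = dm.n_columns
            assert np.all(np.isfinite(dm.values))
            if variant == "SoC":
                assert set(dm.column_block) == {"clinical"}
        assert widths["SoC"] + widths["MassSpec"] + widths["ExoRNA"] == widths["ExoSpec"]

    def test_row_mismatch_is_error(self, small_cohort):
        patients, blocks = small_cohort
        proc = xs.preprocess_cohort(patients, blocks)
        short = xs.OmicsBlock(
            "clinical", proc["clinical"].feature_names, proc["clinical"].values[:-1]
        )
        with pytest.raises(CohortError, match="row"):
            xs.assemble_design(short, proc["peptide"], proc["evrna"], "ExoSpec")


class TestCohortIO:
    def test_round_trip_is_lossless(self, small_cohort, tmp_path):
        patients, blocks = small_cohort
        xs.write_cohort(tmp_path, patients, blocks)
        patients2, blocks2 = xs.read_cohort(tmp_path)
        assert list(patients2["id"]) == list(patients["id"])
        assert list(patients2["stratum"]) == list(patients["stratum"])
        np.testing.assert_array_equal(patients2["psa"], patients["psa"])
        for kind in blocks:
            assert blocks2[kind].feature_names == blocks[kind].feature_names
            np.testing.assert_array_equal(blocks2[kind].values, blocks[kind].values)

    def test_duplicate_patient_id_rejected(self, small_cohort, tmp_path):
        patients, blocks = small_cohort
        bad = patients.copy()
        bad.loc[1, "id"] = bad.loc[0, "id"]
        xs.write_cohort(tmp_path, bad, blocks)
        with pytest.raises(CohortError, match="duplicate"):
            xs.read_cohort(tmp_path)

    def test_non_numeric_psa_names_row(self, small_cohort, tmp_path):
        patients, blocks = small_cohort
        xs.write_cohort(tmp_path, patients, blocks)
        lines = (tmp_path / "patients.tsv").read_text().splitlines()
        parts = lines[3].split("\t")
        parts[2] = "not-a-number"
        lines[3] = "\t".join(parts)
        (tmp_path / "patients.tsv").write_text("\n".join(lines) + "\n")
        with pytest.raises(CohortError, match="row 3"):
            xs.read_cohort(tmp_path)
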