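import numpy as np
import pandas as pd
import pytest

import leptomet as lm
from leptomet.dataio import (
    IntensityParseError,
    SchemaError,
    StudyValidationError,
    validate_metadata,
)

from conftest import make_matrix


def _write_tables(tmp_path, abundance, annotation, metadata):
    pa, pn, pm = tmp_path / "a.tsv", tmp_path / "n.tsv", tmp_path / "m.tsv"
    abundance.to_csv(pa, sep="\t", index=False)
    annotation.to_csv(pn, sep="\t", index=False)
    metadata.to_csv(pm, sep="\t", index=False)
    return pa, pn, pm


@pytest.fixture()
def toy_tables():
    abundance = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "m1": [10.0, 20.0],
            "m2": [1.0, 2.0],
            "m3": [5.0, np.nan],
        }
    )
    annotation = pd.DataFrame(
        {
            "metabolite_id": ["m1", "m2", "m3"],
            "biochemical_name": ["alpha", "beta", "gamma"],
            "super_pathway": ["Lipid"] * 3,
            "sub_pathway": ["sp1", "sp1", "sp2"],
        }
    )
    metadata = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "individual_id": ["i1", "i1"],
            "condition": ["pre", "post"],
            "sex": ["F", "F"],
            "age": [12.0, 12.0],
            "ethnicity": ["x", "x"],
            "run_day": ["d1", "d1"],
        }
    )
    return abundance, annotation, metadata


class TestReadStudy:
    def test_round_trip_shape_and_indices(self, tmp_path, toy_tables):
        paths = _write_tables(tmp_path, *toy_tables)
        matrix, ann, meta = lm.read_study(*paths)
        assert matrix.shape == (2, 3)
        assert list(matrix.sample_ids) == ["s1", "s2"]
        assert list(matrix.metabolite_ids) == ["m1", "m2", "m3"]
        assert not matrix.log_scale

    def test_duplicate_metabolite_id_rejected(self, tmp_path, toy_tables):
        abundance, annotation, metadata = toy_tables
        annotation = pd.concat([annotation, annotation.iloc[[0]]])
        paths = _write_tables(tmp_path, abundance, annotation, metadata)
        with pytest.raises(StudyValidationError, match="m1"):
            lm.read_study(*paths)

    def test_two_pre_samples_for_one_individual_rejected(self, tmp_path, toy_tables):
        abundance, annotation, metadata = toy_tables
        metadata = metadata.assign(condition=["pre", "pre"])
        paths = _write_tables(tmp_path, abundance, annotation, metadata)
        with pytest.raises(StudyValidationError, match="i1"):
            lm.read_study(*paths)

    def test_non_numeric_cell_reports_coordinates(self, tmp_path, toy_tables):
        abundance, annotation, metadata = toy_tables
        abundance["m2"] = abundance["m2"].astype(object)
        abundance.loc[1, "m2"] = "oops"
        paths = _write_tables(tmp_path, abundance, annotation, metadata)
        with pytest.raises(IntensityParseError, match="s2.*m2"):
            lm.read_study(*paths)

    def test_missing_column_named_in_error(self, tmp_path, toy_tables):
        abundance, annotation, metadata = toy_tables
        paths = _write_tables(tmp_path, abundance, annotation.drop(columns=["sub_pathway"]), metadata)
        with pytest.raises(SchemaError, match="sub_pathway"):
            lm.read_study(*paths)

    def test_unknown_metabolite_in_matrix_rejected(self, tmp_path, toy_tables):
        abundance, annotation, metadata = toy_tables
        paths = _write_tables(tmp_path, abundance, annotation.iloc[:2], metadata)
        with pytest.raises(StudyValidationError, match="m3"):
            lm.read_study(*paths)


class TestAgeGroup:
    @pytest.mark.parametrize("age,group", [(18.0, "child"), (18.1, "adult"), (2.0, "child")])
    def test_child_boundary_at_18(self, age, group):
        meta = pd.DataFrame(
            {
                "sample_id": ["s"],
                "individual_id": ["i"],
                "condition": ["pre"],
                "sex": ["F"],
                "age": [age],
                "ethnicity": ["x"],
                "run_day": ["d"],
            }
        )
        assert validate_metadata(meta)["age_group"].iloc[0] == group


class TestImputeAndLog:
    def test_min_imputation_formula(self):
        m = make_matrix([[10.0], [np.nan], [1000.0]], ["a", "b", "c"], ["m1"], log_scale=False)
        out = lm.impute_and_log(m)
        assert out.log_scale
        np.testing.assert_allclose(out.data["m1"].to_numpy(), [1.0, 1.0, 3.0])

    def test_complete_column_is_just_logged(self):
        m = make_matrix([[1.0], [100.0]], ["a", "b"], ["m1"], log_scale=False)
        out = lm.impute_and_log(m)
        np.testing.assert_allclose(out.data["m1"].to_numpy(), [0.0, 2.0])

    def test_halfmin_option(self):
        m = make_matrix([[4.0], [np.nan]], ["a", "b"], ["m1"], log_scale=False)
        out = lm.impute_and_log(m, method="halfmin")
        np.testing.assert_allclose(out.data["m1"].to_numpy(), [np.log10(4), np.log10(2)])

    def test_all_missing_metabolite_dropped_with_warning(self):
        m = make_matrix([[1.0, np.nan], [2.0, np.nan]], ["a", "b"], ["m1", "m2"], log_scale=False)
        with pytest.warns(UserWarning, match="m2"):
            out = lm.impute_and_log(m)
        assert list(out.metabolite_ids) == ["m1"]

    def test_output_always_finite(self, small_study):
        matrix, *_ = small_study
        out = lm.impute_and_log(matrix)
        assert np.isfinite(out.data.to_numpy()).all()


class TestAdjustCovariates:
    def test_empty_covariates_is_identity(self, toy_metadata):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(5, 1, (8, 3)), toy_metadata.index, ["m1", "m2", "m3"])
        out = lm.adjust_covariates(m, toy_metadata, [])
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_exact_fit_leaves_grand_mean(self, toy_metadata):
        # metabolite perfectly predicted by sex: residuals zero, mean kept
        sex = (toy_metadata["sex"] == "F").astype(float)
        m = make_matrix((2.0 * sex).to_numpy()[:, None], toy_metadata.index, ["m1"])
        out = lm.adjust_covariates(m, toy_metadata, ["sex"])
        np.testing.assert_allclose(out.data["m1"].to_numpy(), np.full(8, sex.mean() * 2), atol=1e-12)

    def test_residuals_orthogonal_to_covariate(self, toy_metadata):
        # least-squares contract checked against the normal equations
        age = toy_metadata["age"].to_numpy()
        m = make_matrix((2.0 * age)[:, None], toy_metadata.index, ["m1"])
        out = lm.adjust_covariates(m, toy_metadata, ["age"])
        resid = out.data["m1"].to_numpy() - out.data["m1"].mean()
        assert abs(np.dot(resid, age - age.mean())) < 1e-10

    def test_idempotent(self, toy_metadata):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(5, 1, (8, 4)), toy_metadata.index, list("wxyz"))
        once = lm.adjust_covariates(m, toy_metadata, ["sex", "age"])
        twice = lm.adjust_covariates(once, toy_metadata, ["sex", "age"])
        np.testing.assert_allclose(once.data.to_numpy(), twice.data.to_numpy(), atol=1e-10)

    def test_column_means_preserved(self, toy_metadata):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(5, 1, (8, 4)), toy_metadata.index, list("wxyz"))
        out = lm.adjust_covariates(m, toy_metadata, ["sex", "age", "run_day"])
        np.testing.assert_allclose(
            out.data.mean().to_numpy(), m.data.mean().to_numpy(), atol=1e-10
        )

    def test_condition_refused(self, toy_metadata):
        m = make_matrix(np.zeros((8, 1)) + 5, toy_metadata.index, ["m1"])
        with pytest.raises(StudyValidationError, match="condition"):
            lm.adjust_covariates(m, toy_metadata, ["condition"])

    def test_condition_confounded_covariate_rejected(self, toy_metadata):
        meta = toy_metadata.copy()
        meta["batch"] = np.where(meta["condition"] == "post", "late", "early")
        m = make_matrix(np.random.default_rng(3).normal(size=(8, 2)), meta.index, ["m1", "m2"])
        with pytest.raises(StudyValidationError, match="confounded"):
            lm.adjust_covariates(m, meta, ["batch"])

    def test_overparameterized_design_rejected(self, toy_metadata):
        meta = toy_metadata.copy()
        for k in range(9):
            meta[f"c{k}"] = np.random.default_rng(k).normal(size=8)
        m = make_matrix(np.zeros((8, 1)) + 5, meta.index, ["m1"])
        with pytest.raises(StudyValidationError, match="parameters"):
            lm.adjust_covariates(m, meta, [f"c{k}" for k in range(9)])
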