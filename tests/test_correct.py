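import numpy as np
import pandas as pd
import pytest

from metadrift.correct import (
    CorrectionSpec,
    add_confounder_feature,
    binarize_covariate,
    compare_before_after,
    segment_by_threshold,
    stratified_scale,
)
from metadrift.data import ValidationError
from metadrift.scaling import ScalingSpec, apply_scaler, fit_scaler

from conftest import make_cohort, make_matrix


def cohort_with_ages(values, labels, ages, split=None):
    return make_cohort(values, labels, covariates={"age": ages}, split=split)


class TestBinarizeCovariate:
    def test_boundary_sample_goes_to_lower_stratum(self):
        cohort = cohort_with_ages(np.zeros((3, 2)), ["male", "female", "male"], [20, 26, 30])
        strata = binarize_covariate(cohort.clinical, "age", 26.0)
        assert strata.tolist() == [0, 0, 1]

    def test_degenerate_stratum_warns(self):
        cohort = cohort_with_ages(np.zeros((2, 2)), ["male", "female"], [20, 22])
        with pytest.warns(UserWarning, match="one stratum"):
            strata = binarize_covariate(cohort.clinical, "age", 26.0)
        assert strata.tolist() == [0, 0]

    def test_missing_covariate_values_error(self):
        cohort = cohort_with_ages(np.zeros((2, 2)), ["male", "female"], [20, np.nan])
        with pytest.raises(ValidationError):
            binarize_covariate(cohort.clinical, "age", 26.0)


class TestSegmentByThreshold:
    def test_partition_sizes(self):
        cohort = cohort_with_ages(
            np.zeros((8, 2)),
            ["male", "female"] * 4,
            [20, 21, 24, 25, 30, 31, 33, 35],
            split=["train"] * 8,
        )
        low, high = segment_by_threshold(cohort, CorrectionSpec(covariate="age", threshold=26.0))
        assert low.matrix.n_samples == 4
        assert high.matrix.n_samples == 4

    def test_empty_stratum_errors(self):
        cohort = cohort_with_ages(np.zeros((4, 2)), ["male", "female"] * 2, [30, 31, 32, 33])
        with pytest.warns(UserWarning):
            with pytest.raises(ValidationError, match="empty stratum"):
                segment_by_threshold(cohort, CorrectionSpec(covariate="age", threshold=26.0))

    def test_sparse_stratum_advises_stratified_scaling(self):
        cohort = cohort_with_ages(
            np.zeros((5, 2)), ["male", "female", "male", "female", "male"],
            [20, 21, 22, 23, 30],
        )
        with pytest.raises(ValidationError, match="stratified_scaling"):
            segment_by_threshold(cohort, CorrectionSpec(covariate="age", threshold=26.0))

    def test_balanced_median_split(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(18, 75, 400)
        labels = np.where(rng.uniform(size=400) < 0.5, "male", "female")
        cohort = cohort_with_ages(rng.normal(size=(400, 3)), labels, ages)
        threshold = float(np.median(ages))
        low, high = segment_by_threshold(
            cohort, CorrectionSpec(covariate="age", threshold=threshold)
        )
        assert abs(low.matrix.n_samples - 200) <= 1
        assert low.matrix.n_samples + high.matrix.n_samples == 400


class TestStratifiedScale:
    def test_identical_structure_per_stratum(self):
        values = np.array([[1.0], [2.0], [3.0], [11.0], [12.0], [13.0]])
        cohort = cohort_with_ages(
            values, ["male", "female"] * 3, [20, 21, 22, 30, 31, 32]
        )
        strata = binarize_covariate(cohort.clinical, "age", 26.0)
        out = stratified_scale(cohort.matrix, strata, ScalingSpec("autoscaling"))
        np.testing.assert_allclose(out.values[:3, 0], [-1.0, 0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(out.values[3:, 0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_single_stratum_reduces_to_ordinary_scaling(self):
        values = np.arange(8.0).reshape(4, 2)
        cohort = cohort_with_ages(values, ["male", "female"] * 2, [20, 21, 22, 23])
        with pytest.warns(UserWarning):
            strata = binarize_covariate(cohort.clinical, "age", 26.0)
        with pytest.warns(UserWarning, match="single stratum"):
            out = stratified_scale(cohort.matrix, strata, ScalingSpec("autoscaling"))
        spec = ScalingSpec("autoscaling")
        plain = apply_scaler(cohort.matrix, fit_scaler(cohort.matrix, spec), spec)
        np.testing.assert_allclose(out.values, plain.values, atol=1e-12)

    def test_infinite_threshold_equals_ordinary_scaling(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(size=(20, 4))
        cohort = cohort_with_ages(
            values, ["male", "female"] * 10, rng.uniform(18, 75, 20)
        )
        with pytest.warns(UserWarning):
            strata = binarize_covariate(cohort.clinical, "age", np.finfo(float).max)
        with pytest.warns(UserWarning):
            out = stratified_scale(cohort.matrix, strata, ScalingSpec("pareto"))
        spec = ScalingSpec("pareto")
        plain = apply_scaler(cohort.matrix, fit_scaler(cohort.matrix, spec), spec)
        np.testing.assert_allclose(out.values, plain.values, atol=1e-12)

    def test_preserves_sample_count_and_order(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(30, 3))
        ages = rng.uniform(18, 75, 30)
        cohort = cohort_with_ages(values, ["male", "female"] * 15, ages)
        strata = binarize_covariate(cohort.clinical, "age", 40.0)
        out = stratified_scale(cohort.matrix, strata, ScalingSpec("centering"))
        assert out.sample_ids == cohort.matrix.sample_ids

    def test_between_stratum_mean_gap_removed(self):
        rng = np.random.default_rng(4)
        low_block = rng.normal(0.0, 1.0, (50, 2))
        high_block = rng.normal(10.0, 1.0, (50, 2))
        cohort = cohort_with_ages(
            np.vstack([low_block, high_block]),
            ["male", "female"] * 50,
            [20.0] * 50 + [40.0] * 50,
        )
        strata = binarize_covariate(cohort.clinical, "age", 30.0)
        out = stratified_scale(cohort.matrix, strata, ScalingSpec("centering"))
        gap = out.values[50:].mean(axis=0) - out.values[:50].mean(axis=0)
        np.testing.assert_allclose(gap, 0.0, atol=1e-10)

    def test_fit_split_must_contain_both_strata(self):
        values = np.zeros((4, 1))
        cohort = cohort_with_ages(values, ["male", "female"] * 2, [20, 21, 40, 41])
        strata = binarize_covariate(cohort.clinical, "age", 26.0)
        with pytest.raises(ValidationError, match="absent from the fitting split"):
            stratified_scale(
                cohort.matrix, strata, ScalingSpec("centering"),
                fit_sample_ids=cohort.sample_ids[:2],
            )


class TestAddConfounderFeature:
    def test_appends_binary_column(self):
        m = make_matrix(np.zeros((3, 2)))
        strata = pd.Series([0, 1, 1], index=m.data.index, name="age>26")
        out = add_confounder_feature(m, strata)
        assert out.feature_ids[-1] == "age>26"
        assert out.values[:, -1].tolist() == [0.0, 1.0, 1.0]


class TestCompareBeforeAfter:
    def _metrics(self, acc, warn, drift):
        return dict(accuracy=acc, warning_count=warn, drift_count=drift)

    def test_identical_runs_have_zero_deltas(self):
        cells = {("knn", "autoscaling"): self._metrics(0.7, 2, 1)}
        report = compare_before_after(cells, dict(cells), CorrectionSpec(covariate="age"))
        entry = report.entries[0]
        assert entry.accuracy_delta == 0.0
        assert entry.drift_count_before == entry.drift_count_after == 1

    def test_delta_recorded(self):
        before = {("knn", "autoscaling"): self._metrics(0.58, 3, 1)}
        after = {("knn", "autoscaling"): self._metrics(0.61, 1, 0)}
        report = compare_before_after(before, after, CorrectionSpec(covariate="age"))
        entry = report.entries[0]
        assert entry.accuracy_delta == pytest.approx(0.03)
        frame = report.to_frame()
        assert bool(frame["drift_free_after"].iloc[0])

    def test_mismatched_cells_error(self):
        before = {("knn", "autoscaling"): self._metrics(0.5, 0, 0)}
        after = {("rf", "autoscaling"): self._metrics(0.5, 0, 0)}
        with pytest.raises(ValidationError, match="mismatched run configurations"):
            compare_before_after(before, after, CorrectionSpec(covariate="age"))
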