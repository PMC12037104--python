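import numpy as np
import pandas as pd
import pytest

from metadrift.data import ValidationError
from metadrift.harmonize import (
    AmbiguousMappingError,
    flag_outliers,
    impute_half_min,
    intersect_features,
    map_identifiers,
    remove_outliers,
    split_dataset,
)

from conftest import make_cohort, make_matrix
from oracles import outlier_oracle


class TestMapIdentifiers:
    def test_direct_lookup_renames_feature(self):
        m = make_matrix([[1.0], [2.0]], feature_ids=["Creatinine"])
        out, report = map_identifiers(m, {"Creatinine": "C00791"})
        assert out.feature_ids == ["C00791"]
        assert report.dropped == []

    def test_empty_mapping_drops_everything(self):
        m = make_matrix(np.ones((2, 5)), feature_ids=list("abcde"))
        out, report = map_identifiers(m, {})
        assert out.n_features == 0
        assert sorted(report.dropped) == list("abcde")

    def test_collision_raises_and_names_both(self):
        m = make_matrix(np.ones((2, 2)), feature_ids=["Serine", "L-Serine"])
        with pytest.raises(AmbiguousMappingError, match="Serine.*L-Serine|L-Serine.*Serine"):
            map_identifiers(m, {"Serine": "C00065", "L-Serine": "C00065"})

    def test_malformed_kegg_id_rejected(self):
        m = make_matrix([[1.0]], feature_ids=["x"])
        with pytest.raises(ValidationError, match="malformed"):
            map_identifiers(m, {"x": "K00001"})


class TestIntersectFeatures:
    def test_pairwise_intersection(self):
        a = make_matrix(np.ones((2, 3)), feature_ids=["A", "B", "C"])
        b = make_matrix(np.ones((3, 3)), feature_ids=["B", "C", "D"])
        out = intersect_features([a, b])
        assert [m.feature_ids for m in out] == [["B", "C"], ["B", "C"]]
        assert out[0].n_samples == 2 and out[1].n_samples == 3

    def test_identical_feature_sets_unchanged(self):
        ids = [f"C{i:05d}" for i in range(22)]
        mats = [make_matrix(np.random.default_rng(i).normal(size=(4, 22)), feature_ids=ids)
                for i in range(3)]
        out = intersect_features(mats)
        assert all(m.feature_ids == sorted(ids) for m in out)
        assert all(m.n_features == 22 for m in out)

    def test_empty_intersection_errors_with_counts(self):
        a = make_matrix([[1.0]], feature_ids=["A"])
        b = make_matrix([[1.0]], feature_ids=["B"])
        with pytest.raises(ValidationError, match="1, 1"):
            intersect_features([a, b])

    def test_matches_brute_force_set_intersection(self):
        rng = np.random.default_rng(0)
        universe = [f"C{i:05d}" for i in range(40)]
        mats = []
        for i in range(3):
            ids = sorted(rng.choice(universe, size=25, replace=False))
            mats.append(make_matrix(rng.normal(size=(3, 25)), feature_ids=ids))
        expected = set(mats[0].feature_ids)
        for m in mats[1:]:
            expected &= set(m.feature_ids)
        out = intersect_features(mats)
        assert all(set(m.feature_ids) == expected for m in out)


class TestImputeHalfMin:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([2.0, 4.0, np.nan, 8.0], [2.0, 4.0, 1.0, 8.0]),
            ([0.4, np.nan], [0.4, 0.2]),
        ],
    )
    def test_fills_half_of_column_minimum(self, column, expected):
        m = make_matrix(np.array(column)[:, None])
        out = impute_half_min(m)
        np.testing.assert_array_equal(out.values[:, 0], expected)
        assert not out.missing_mask.to_numpy().any()

    def test_idempotent_and_preserves_observed(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(size=(20, 5))
        values[rng.uniform(size=values.shape) < 0.2] = np.nan
        m = make_matrix(values)
        once = impute_half_min(m)
        twice = impute_half_min(once)
        np.testing.assert_array_equal(once.values, twice.values)
        observed = ~np.isnan(values)
        np.testing.assert_array_equal(once.values[observed], values[observed])

    def test_all_missing_column_errors(self):
        m = make_matrix(np.array([[np.nan], [np.nan]]))
        with pytest.raises(ValidationError, match="C00001"):
            impute_half_min(m)


class TestFlagOutliers:
    def test_constant_column_flags_nothing(self):
        m = make_matrix(np.full((4, 1), 5.0))
        groups = pd.Series(["a"] * 4, index=m.data.index)
        assert not flag_outliers(m, groups).to_numpy().any()

    def test_hand_computed_single_spike(self):
        # mean 0.9, sd (n-1) = 2.846, threshold 5.69: only the 9 is outside
        col = np.array([0.0] * 9 + [9.0])
        m = make_matrix(col[:, None])
        groups = pd.Series(["a"] * 10, index=m.data.index)
        flags = flag_outliers(m, groups).to_numpy()[:, 0]
        assert flags.tolist() == [False] * 9 + [True]

    def test_identical_groups_get_identical_flags(self):
        rng = np.random.default_rng(2)
        block = rng.normal(size=(10, 3))
        m = make_matrix(np.vstack([block, block]))
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=m.data.index)
        flags = flag_outliers(m, groups).to_numpy()
        np.testing.assert_array_equal(flags[:10], flags[10:])

    def test_singleton_group_errors(self):
        m = make_matrix([[1.0], [2.0], [3.0]])
        groups = pd.Series(["a", "a", "b"], index=m.data.index)
        with pytest.raises(ValidationError, match="single sample"):
            flag_outliers(m, groups)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(50, 10))
        m = make_matrix(values)
        groups = pd.Series(rng.choice(["a", "b"], size=50), index=m.data.index)
        flags = flag_outliers(m, groups).to_numpy()
        np.testing.assert_array_equal(flags, outlier_oracle(values, groups.to_numpy()))

    def test_remove_outliers_keeps_shape_and_reports(self):
        col = np.array([0.0] * 9 + [9.0])
        m = make_matrix(np.column_stack([col, np.ones(10)]))
        groups = pd.Series(["a"] * 10, index=m.data.index)
        cleaned, report = remove_outliers(m, groups)
        assert cleaned.values.shape == (10, 2)
        assert len(report) == 1
        assert report.iloc[0]["feature_id"] == "C00001"
        # flagged spike replaced by half of the remaining minimum (0 -> 0)
        assert cleaned.values[9, 0] == 0.0


class TestSplitDataset:
    def _cohort(self, n=10):
        labels = ["male", "female"] * (n // 2)
        return make_cohort(np.random.default_rng(0).normal(size=(n, 3)), labels)

    def test_stratified_8_2(self):
        ds = split_dataset(self._cohort(10), 0.2, seed=1)
        assert len(ds.samples_in("train")) == 8
        test = ds.samples_in("test")
        assert len(test) == 2
        assert set(ds.clinical.labels.loc[test]) == {"male", "female"}

    def test_deterministic_for_fixed_seed(self):
        a = split_dataset(self._cohort(), 0.2, seed=3)
        b = split_dataset(self._cohort(), 0.2, seed=3)
        pd.testing.assert_series_equal(a.split, b.split)

    def test_80_20_at_n_100(self):
        ds = split_dataset(self._cohort(100), 0.2, seed=42)
        assert len(ds.samples_in("train")) == 80
        assert len(ds.samples_in("test")) == 20

    def test_per_class_fraction_close(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(["male", "female"], size=97, p=[0.4, 0.6])
        cohort = make_cohort(rng.normal(size=(97, 2)), labels)
        ds = split_dataset(cohort, 0.25, seed=0)
        for cls in ("male", "female"):
            ids = ds.clinical.labels[ds.clinical.labels == cls].index
            frac = (ds.split.loc[ids] == "test").mean()
            assert abs(frac - 0.25) < 1.0 / len(ids)

    def test_tiny_class_errors(self):
        cohort = make_cohort(np.zeros((3, 2)), ["male", "male", "female"])
        with pytest.raises(ValidationError):
            split_dataset(cohort, 0.5, seed=0)
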