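import numpy as np
import pandas as pd
import pytest

from metadrift.classify import PredictionResult
from metadrift.data import ClinicalTable, ValidationError
from metadrift.drift import (
    DetectorConfig,
    ErrorStream,
    build_error_stream,
    confirmed_events,
    ddm_detect,
    eddm_detect,
)
from metadrift.simulate import generate_error_stream

from oracles import ddm_oracle, eddm_oracle


def stream_of(errors):
    errors = np.asarray(errors, dtype=int)
    return ErrorStream([f"s{i}" for i in range(len(errors))], errors)


class TestBuildErrorStream:
    def _clinical(self, ages, ids):
        return ClinicalTable(
            pd.DataFrame({"sex": ["male"] * len(ids), "age": ages}, index=ids),
            target="sex",
        )

    def test_dataset_order_errors(self):
        result = PredictionResult(["a", "b", "c"], np.array(["M", "F", "M"]),
                                  np.array(["M", "M", "M"]), 2 / 3)
        stream = build_error_stream(result, self._clinical([1, 2, 3], ["a", "b", "c"]))
        assert stream.errors.tolist() == [0, 1, 0]
        assert stream.sample_ids == ["a", "b", "c"]

    def test_covariate_ordering_sorts_ascending(self):
        ids = ["a", "b", "c"]
        result = PredictionResult(ids, np.array(["M"] * 3), np.array(["M"] * 3), 1.0)
        stream = build_error_stream(result, self._clinical([30, 20, 25], ids), "age")
        assert stream.sample_ids == ["b", "c", "a"]

    def test_ties_broken_by_sample_id_stably(self):
        ids = ["z", "a", "m"]
        result = PredictionResult(ids, np.array(["M"] * 3), np.array(["M"] * 3), 1.0)
        clinical = self._clinical([5, 5, 5], ids)
        first = build_error_stream(result, clinical, "age")
        second = build_error_stream(result, clinical, "age")
        assert first.sample_ids == second.sample_ids == ["a", "m", "z"]

    def test_unknown_key_and_missing_values_error(self):
        ids = ["a", "b"]
        result = PredictionResult(ids, np.array(["M", "M"]), np.array(["M", "M"]), 1.0)
        clinical = self._clinical([1.0, np.nan], ids)
        with pytest.raises(KeyError):
            build_error_stream(result, clinical, "bmi")
        with pytest.raises(ValidationError, match="'b'"):
            build_error_stream(result, clinical, "age")


class TestDDM:
    def test_all_zeros_never_fires(self):
        assert ddm_detect(stream_of(np.zeros(100))) == []

    def test_analytic_trace_30_zeros_one_error(self):
        """With a zero-error baseline any error exceeds p_min + 3 s_min."""
        events = ddm_detect(stream_of([0] * 30 + [1]))
        drifts = [e for e in events if e.level == "drift"]
        assert len(drifts) == 1
        assert drifts[0].index == 30
        assert drifts[0].stats_at_trigger["s_min"] == 0.0
        # the degenerate-baseline filter removes exactly this event
        assert confirmed_events(events) == []

    def test_step_change_detected_after_change_point(self):
        stream = generate_error_stream(1000, [(0, 0.05), (500, 0.5)], seed=7)
        drifts = [e for e in ddm_detect(stream) if e.level == "drift"]
        assert drifts and any(e.index >= 500 for e in drifts)

    def test_warning_precedes_or_coincides_with_drift(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(50, 500))
            errors = (rng.uniform(size=n) < rng.uniform(0.02, 0.4)).astype(int)
            events = ddm_detect(stream_of(errors))
            last_warning = None
            for ev in events:
                if ev.level == "warning":
                    last_warning = ev.index
                else:
                    assert last_warning is not None and last_warning <= ev.index
                    last_warning = None

    def test_empty_stream_errors(self):
        with pytest.raises(ValidationError):
            ddm_detect(stream_of([]))

    @pytest.mark.parametrize("seed", range(20))
    def test_streaming_equals_from_scratch_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 2000))
        rate = rng.uniform(0.01, 0.5)
        errors = (rng.uniform(size=n) < rate).astype(int)
        events = [(e.index, e.level) for e in ddm_detect(stream_of(errors))]
        assert events == ddm_oracle(errors)


class TestEDDM:
    def test_fewer_than_two_errors_no_events(self):
        assert eddm_detect(stream_of([0] * 50 + [1] + [0] * 50)) == []

    def test_all_ones_is_stationary(self):
        assert eddm_detect(stream_of(np.ones(200))) == []

    def test_spacing_change_triggers_drift(self):
        errors = np.zeros(40 * 20 + 1200, dtype=int)
        errors[::20] = 1  # one error every 20 instances through the first block
        errors[40 * 20 :: 2] = 1  # then every 2 instances
        events = eddm_detect(stream_of(errors))
        drifts = [e for e in events if e.level == "drift"]
        assert drifts and drifts[0].index > 40 * 20
        # exact position pinned by the independent recomputation
        assert [(e.index, e.level) for e in events] == eddm_oracle(errors)

    @pytest.mark.parametrize("seed", range(20))
    def test_streaming_equals_from_scratch_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(50, 2000))
        rate = rng.uniform(0.01, 0.5)
        errors = (rng.uniform(size=n) < rate).astype(int)
        events = [(e.index, e.level) for e in eddm_detect(stream_of(errors))]
        assert events == eddm_oracle(errors)

    def test_warning_precedes_or_coincides_with_drift(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(200, 1500))
            first = (rng.uniform(size=n // 2) < 0.05).astype(int)
            second = (rng.uniform(size=n - n // 2) < 0.4).astype(int)
            events = eddm_detect(stream_of(np.concatenate([first, second])))
            last_warning = None
            for ev in events:
                if ev.level == "warning":
                    last_warning = ev.index
                else:
                    assert last_warning is not None and last_warning <= ev.index
                    last_warning = None


class TestDetectorConfig:
    def test_threshold_ordering_enforced(self):
        from metadrift.drift import DDMConfig, EDDMConfig

        with pytest.raises(ValidationError):
            DDMConfig(warning_sigma=3.0, drift_sigma=2.0)
        with pytest.raises(ValidationError):
            EDDMConfig(alpha=0.8, beta=0.9)

    def test_custom_config_changes_sensitivity(self):
        stream = generate_error_stream(400, [(0, 0.05), (200, 0.6)], seed=3)
        loose = DetectorConfig()
        loose.ddm.min_instances = 5
        default_drifts = sum(e.level == "drift" for e in ddm_detect(stream))
        loose_drifts = sum(e.level == "drift" for e in ddm_detect(stream, loose))
        assert loose_drifts >= default_drifts
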