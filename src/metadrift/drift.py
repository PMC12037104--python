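"""Concept-drift detection on ordered binary misclassification streams.

Implements the two classical prequential error monitors from the drift
detection literature in their original published forms:

DDM (drift detection method)
    Tracks the running error rate :math:`p_i` over the *i* instances seen
    since the last reset and its binomial standard deviation
    :math:`s_i = \\sqrt{p_i (1-p_i) / i}`, together with the historical
    minimum of :math:`p_i + s_i` (stored as the pair ``p_min, s_min``).
    Once at least ``min_instances`` have been seen, the detector signals a
    *warning* when :math:`p_i + s_i > p_{min} + 2\\,s_{min}` and a *drift*
    when :math:`p_i + s_i > p_{min} + 3\\,s_{min}`; a drift resets all state.

EDDM (early drift detection method)
    Monitors the distances (in instances) between consecutive errors,
    maintaining their running mean :math:`p'_i` and standard deviation
    :math:`s'_i` and the historical maximum of :math:`p'_i + 2 s'_i`.
    After at least ``min_errors`` distances, a *warning* is signalled when
    :math:`(p'_i + 2 s'_i)/(p'_{max} + 2 s'_{max}) < \\alpha` and a *drift*
    when the ratio falls below :math:`\\beta`; a drift resets all state.

Both detectors run post hoc over the error stream of a fixed, already
trained classifier; nothing is updated online. Every drift is preceded by
(or coincides with) a warning within its episode. A DDM event raised while
the historical baseline contains no error at all (``s_min == 0``, where the
3-sigma binomial test degenerates) is flagged so downstream analysis can
treat it separately; see :func:`confirmed_events`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metadrift.classify import PredictionResult
from metadrift.data import ClinicalTable, ValidationError

LEVELS = ("warning", "drift")


@dataclass
class ErrorStream:
    """Ordered binary misclassification sequence (1 = misclassified)."""

    sample_ids: list[str]
    errors: np.ndarray
    ordering_key: str = "dataset_order"

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=int)
        if self.errors.ndim != 1 or len(self.errors) != len(self.sample_ids):
            raise ValidationError("errors must be a 1-d sequence aligned with sample_ids")
        if not np.isin(self.errors, (0, 1)).all():
            raise ValidationError("errors must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.errors)


@dataclass
class DriftEvent:
    """A detector trigger: position, severity and the statistics at trigger."""

    index: int
    level: str
    detector: str
    stats_at_trigger: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"level must be one of {LEVELS}")


@dataclass
class DDMConfig:
    min_instances: int = 30
    warning_sigma: float = 2.0
    drift_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.min_instances < 1:
            raise ValidationError("min_instances must be >= 1")
        if not self.warning_sigma < self.drift_sigma:
            raise ValidationError("warning threshold must be looser than drift threshold")


@dataclass
class EDDMConfig:
    min_errors: int = 30
    alpha: float = 0.95
    beta: float = 0.90

    def __post_init__(self) -> None:
        if self.min_errors < 1:
            raise ValidationError("min_errors must be >= 1")
        if not self.beta < self.alpha:
            raise ValidationError("alpha (warning) must exceed beta (drift)")


@dataclass
class DetectorConfig:
    ddm: DDMConfig = field(default_factory=DDMConfig)
    eddm: EDDMConfig = field(default_factory=EDDMConfig)


class DDM:
    """Streaming DDM state machine; ``update`` returns events at this index."""

    name = "ddm"

    def __init__(self, config: DDMConfig | None = None):
        self.config = config or DDMConfig()
        self.reset()

    def reset(self) -> None:
        self._n = 0
        self._n_errors = 0
        self.p_min = math.inf
        self.s_min = math.inf
        self._in_warning_zone = False
        self._episode_has_warning = False

    def update(self, error: int, index: int) -> list[DriftEvent]:
        cfg = self.config
        self._n += 1
        self._n_errors += int(error)
        p = self._n_errors / self._n
        s = math.sqrt(p * (1.0 - p) / self._n)
        if self._n < cfg.min_instances:
            return []
        if p + s < self.p_min + self.s_min:
            self.p_min, self.s_min = p, s
        stats = {"p_i": p, "s_i": s, "p_min": self.p_min, "s_min": self.s_min}
        events: list[DriftEvent] = []
        if p + s > self.p_min + cfg.drift_sigma * self.s_min:
            if not self._episode_has_warning:
                events.append(DriftEvent(index, "warning", self.name, dict(stats)))
            events.append(DriftEvent(index, "drift", self.name, dict(stats)))
            self.reset()
        elif p + s > self.p_min + cfg.warning_sigma * self.s_min:
            if not self._in_warning_zone:
                events.append(DriftEvent(index, "warning", self.name, dict(stats)))
                self._in_warning_zone = True
                self._episode_has_warning = True
        else:
            self._in_warning_zone = False
        return events


class EDDM:
    """Streaming EDDM state machine over distances between errors."""

    name = "eddm"

    def __init__(self, config: EDDMConfig | None = None):
        self.config = config or EDDMConfig()
        self.reset()

    def reset(self) -> None:
        self._last_error_index: int | None = None
        self._n_dist = 0
        self._sum = 0.0
        self._sum_sq = 0.0
        self.p_max = -math.inf
        self.s_max = -math.inf
        self._in_warning_zone = False
        self._episode_has_warning = False

    def update(self, error: int, index: int) -> list[DriftEvent]:
        if not error:
            return []
        cfg = self.config
        if self._last_error_index is None:
            self._last_error_index = index
            return []
        distance = index - self._last_error_index
        self._last_error_index = index
        self._n_dist += 1
        self._sum += distance
        self._sum_sq += distance * distance
        mean = self._sum / self._n_dist
        # population sd from running sums (distances are small integers, so
        # the sums stay exactly representable)
        sd = math.sqrt(max(self._sum_sq / self._n_dist - mean * mean, 0.0))
        self._mean = mean
        level = mean + 2.0 * sd
        events: list[DriftEvent] = []
        if level > self.p_max + 2.0 * self.s_max:
            self.p_max, self.s_max = self._mean, sd
            self._in_warning_zone = False
            return []
        if self._n_dist < cfg.min_errors:
            return []
        ratio = level / (self.p_max + 2.0 * self.s_max)
        stats = {"p_i": self._mean, "s_i": sd, "p_max": self.p_max,
                 "s_max": self.s_max, "ratio": ratio}
        if ratio < cfg.beta:
            if not self._episode_has_warning:
                events.append(DriftEvent(index, "warning", self.name, dict(stats)))
            events.append(DriftEvent(index, "drift", self.name, dict(stats)))
            self.reset()
        elif ratio < cfg.alpha:
            if not self._in_warning_zone:
                events.append(DriftEvent(index, "warning", self.name, dict(stats)))
                self._in_warning_zone = True
                self._episode_has_warning = True
        else:
            self._in_warning_zone = False
        return events


def _run_detector(detector, stream: ErrorStream) -> list[DriftEvent]:
    if len(stream) == 0:
        raise ValidationError("cannot run a drift detector on an empty stream")
    events: list[DriftEvent] = []
    for index, error in enumerate(stream.errors):
        events.extend(detector.update(int(error), index))
    return events


def ddm_detect(stream: ErrorStream, config: DetectorConfig | None = None) -> list[DriftEvent]:
    """All DDM warning/drift events over a stream, in order."""
    cfg = (config or DetectorConfig()).ddm
    return _run_detector(DDM(cfg), stream)


def eddm_detect(stream: ErrorStream, config: DetectorConfig | None = None) -> list[DriftEvent]:
    """All EDDM warning/drift events over a stream, in order."""
    cfg = (config or DetectorConfig()).eddm
    return _run_detector(EDDM(cfg), stream)


def confirmed_events(events: list[DriftEvent]) -> list[DriftEvent]:
    """Drop DDM events triggered from an all-zero baseline.

    When no error has contributed to the historical minimum (``s_min == 0``
    and ``p_min == 0``), the DDM trigger condition reduces to "any error at
    all", which is not a 2/3-sigma binomial test. Such events indicate a
    degenerate baseline rather than evidence of drift, so confounder
    nomination and before/after reporting exclude them. EDDM events are
    unaffected (its statistic requires ``min_errors`` observed distances).
    """
    kept = []
    for ev in events:
        if ev.detector == "ddm" and ev.stats_at_trigger.get("s_min", 1.0) == 0.0:
            continue
        kept.append(ev)
    return kept


def build_error_stream(
    result: PredictionResult, clinical: ClinicalTable, ordering_key: str = "dataset_order"
) -> ErrorStream:
    """Order prediction errors by a covariate (or keep dataset order).

    Samples are sorted ascending by the covariate with a stable tie-break on
    sample ID, so equal covariate values always produce the same stream.
    """
    ids = list(result.sample_ids)
    errors = result.errors
    if ordering_key == "dataset_order":
        return ErrorStream(ids, errors, ordering_key)
    values = clinical.covariate(ordering_key)
    missing_ids = set(ids) - set(values.index)
    if missing_ids:
        raise ValidationError(f"samples absent from clinical table: {sorted(missing_ids)}")
    values = values.loc[ids]
    if values.isna().any():
        bad = values.index[values.isna()].tolist()
        raise ValidationError(
            f"covariate {ordering_key!r} missing for samples {bad}; cannot order stream"
        )
    frame = pd.DataFrame({"value": values.to_numpy(), "sample_id": ids, "error": errors})
    frame = frame.sort_values(["value", "sample_id"], kind="mergesort")
    return ErrorStream(frame["sample_id"].tolist(), frame["error"].to_numpy(), ordering_key)


def events_table(
    events: list[DriftEvent], stream: ErrorStream, clinical: ClinicalTable | None = None
) -> pd.DataFrame:
    """Flat event table for reporting (one row per event)."""
    rows = []
    for ev in events:
        sid = stream.sample_ids[ev.index]
        row = dict(
            detector=ev.detector,
            level=ev.level,
            index=ev.index,
            ordered_sample_id=sid,
            ordering_key=stream.ordering_key,
        )
        if clinical is not None and stream.ordering_key != "dataset_order":
            row["covariate_value"] = clinical.covariate(stream.ordering_key).loc[sid]
        for key, value in ev.stats_at_trigger.items():
            row[f"stat_{key}"] = value
        rows.append(row)
    return pd.DataFrame(rows)
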