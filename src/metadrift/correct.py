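"""Model correction once a confounding factor and threshold are known.

Two strategies, mirroring the two correction hypotheses of the workflow:

segmentation
    Partition the cohort at the confounder threshold and train one model per
    stratum. Statistically clean — each stratum is internally homogeneous —
    but halves the data available to each model, so it needs cohorts large
    enough to afford the split.

stratified scaling
    Keep every sample: fit the scaling parameters separately within each
    stratum (on training samples) and apply them stratum-wise, optionally
    appending the binarized confounder as an input feature so that models
    able to represent interactions can condition on the stratum. No sample
    is lost and the sample order is untouched.

Boundary samples (value == threshold) go to the lower stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from metadrift.data import ClinicalTable, CohortDataset, MetaboliteMatrix, ValidationError
from metadrift.scaling import AbundanceScaler, ScalingSpec


@dataclass
class CorrectionSpec:
    """How to correct a model for a nominated confounder."""

    strategy: str = "stratified_scaling"
    covariate: str = "age"
    threshold: float = 26.0
    scaling: ScalingSpec = field(default_factory=ScalingSpec)
    add_indicator: bool = True  # append the binary confounder column (stratified_scaling)
    refit: bool = True  # refit classifier hyperparameters after correction

    def __post_init__(self) -> None:
        if self.strategy not in ("segmentation", "stratified_scaling"):
            raise ValidationError(
                "strategy must be 'segmentation' or 'stratified_scaling'"
            )
        if not np.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")


def binarize_covariate(clinical: ClinicalTable, covariate: str, threshold: float) -> pd.Series:
    """Per-sample stratum: 0 where value <= threshold, else 1."""
    values = clinical.covariate(covariate)
    if values.isna().any():
        bad = values.index[values.isna()].tolist()
        raise ValidationError(f"covariate {covariate!r} missing for samples {bad}")
    strata = (values > threshold).astype(int)
    strata.name = f"{covariate}>{threshold:g}"
    if strata.nunique() < 2:
        warnings.warn(
            f"threshold {threshold:g} puts all samples in one stratum of "
            f"{covariate!r}; correction degenerates to the uncorrected model"
        )
    return strata


def segment_by_threshold(
    dataset: CohortDataset, spec: CorrectionSpec
) -> tuple[CohortDataset, CohortDataset]:
    """Split a cohort into (low, high) strata at the confounder threshold.

    Each stratum keeps its own train/test assignment so per-stratum models
    remain comparable with the uncorrected run.
    """
    strata = binarize_covariate(dataset.clinical, spec.covariate, spec.threshold)
    low_ids = strata.index[strata == 0].tolist()
    high_ids = strata.index[strata == 1].tolist()
    if not low_ids or not high_ids:
        raise ValidationError(
            f"threshold {spec.threshold:g} leaves an empty stratum of {spec.covariate!r}"
        )
    out = []
    for name, ids in (("low", low_ids), ("high", high_ids)):
        sub = dataset.subset(ids)
        counts = sub.clinical.labels.value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise ValidationError(
                f"stratum {name!r} ({spec.covariate} {'<=' if name == 'low' else '>'} "
                f"{spec.threshold:g}) has under 2 samples in some class; "
                "segmentation needs a significant amount of data — "
                "consider the stratified_scaling strategy instead"
            )
        out.append(sub)
    return out[0], out[1]


class StratifiedScaler(BaseEstimator, TransformerMixin):
    """Per-stratum metabolomics scaling.

    Fits one :class:`AbundanceScaler` per stratum of a binary confounder
    indicator and applies each stratum's parameters to its own members.
    Output shape equals input shape and the sample order is preserved — the
    advantage of this correction over segmentation.

    ``fit`` and ``transform`` take the per-sample stratum labels through the
    ``strata`` keyword (0/1 integers aligned with rows).
    """

    def __init__(self, method: str = "autoscaling", epsilon: float = 1e-12,
                 power_exponent: float = 0.5, log_offset: bool = False):
        self.method = method
        self.epsilon = epsilon
        self.power_exponent = power_exponent
        self.log_offset = log_offset

    def _new_scaler(self) -> AbundanceScaler:
        return AbundanceScaler(self.method, self.epsilon, self.power_exponent, self.log_offset)

    def fit(self, X, y=None, *, strata):
        frame = AbundanceScaler._as_frame(X)
        strata = np.asarray(strata, dtype=int)
        if len(strata) != len(frame):
            raise ValidationError("strata must align with the rows of X")
        self.strata_levels_ = np.unique(strata)
        if len(self.strata_levels_) == 1:
            warnings.warn(
                "single stratum in fitting data; stratified scaling reduces "
                "to ordinary scaling"
            )
        self.scalers_ = {}
        for level in self.strata_levels_:
            block = frame.iloc[strata == level]
            if len(block) == 1 and self.method in ("autoscaling", "pareto", "vast"):
                warnings.warn(
                    f"stratum {level} has a single member; sd-based scaling "
                    "passes its centered values through"
                )
            self.scalers_[int(level)] = self._new_scaler().fit(block)
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X, *, strata):
        check_is_fitted(self, "scalers_")
        frame = AbundanceScaler._as_frame(X)
        strata = np.asarray(strata, dtype=int)
        if len(strata) != len(frame):
            raise ValidationError("strata must align with the rows of X")
        unseen = set(np.unique(strata)) - set(self.scalers_)
        if unseen:
            raise ValidationError(f"strata {sorted(unseen)} were not present at fit time")
        out = frame.copy().astype(float)
        for level, scaler in self.scalers_.items():
            mask = strata == level
            if mask.any():
                out.iloc[mask] = scaler.transform(frame.iloc[mask]).to_numpy()
        if isinstance(X, MetaboliteMatrix):
            return MetaboliteMatrix(out)
        if isinstance(X, pd.DataFrame):
            return out
        return out.to_numpy()


def stratified_scale(
    matrix: MetaboliteMatrix,
    binary_class: pd.Series,
    spec: ScalingSpec,
    fit_sample_ids: list[str] | None = None,
) -> MetaboliteMatrix:
    """Scale each stratum with its own train-fitted parameters.

    ``fit_sample_ids`` restricts parameter estimation (normally to the
    training split); parameters are then applied to all rows of the matrix,
    stratum-wise. Sample count and order are unchanged.
    """
    strata = binary_class.loc[matrix.data.index].to_numpy(dtype=int)
    scaler = StratifiedScaler(spec.method, spec.epsilon, spec.power_exponent, spec.log_offset)
    if fit_sample_ids is None:
        scaler.fit(matrix, strata=strata)
    else:
        fit_matrix = matrix.select_samples(fit_sample_ids)
        fit_strata = binary_class.loc[fit_sample_ids].to_numpy(dtype=int)
        missing = set(np.unique(strata)) - set(np.unique(fit_strata))
        if missing:
            raise ValidationError(
                f"strata {sorted(missing)} absent from the fitting split; "
                "both classes must be present to fit per-stratum parameters"
            )
        scaler.fit(fit_matrix, strata=fit_strata)
    return scaler.transform(matrix, strata=strata)


def add_confounder_feature(
    matrix: MetaboliteMatrix, binary_class: pd.Series, name: str | None = None
) -> MetaboliteMatrix:
    """Append the binarized confounder as an input column (the two-column pairing)."""
    name = name or str(binary_class.name or "confounder_class")
    data = matrix.data.copy()
    if name in data.columns:
        raise ValidationError(f"matrix already has a column named {name!r}")
    data[name] = binary_class.loc[data.index].astype(float)
    return MetaboliteMatrix(data)


@dataclass
class ComparisonEntry:
    classifier: str
    scaling: str
    accuracy_before: float
    accuracy_after: float
    warning_count_before: int
    warning_count_after: int
    drift_count_before: int
    drift_count_after: int

    @property
    def accuracy_delta(self) -> float:
        return self.accuracy_after - self.accuracy_before


@dataclass
class ComparisonReport:
    """Paired before/after metrics for each classifier x scaling cell."""

    entries: list[ComparisonEntry]
    correction: CorrectionSpec

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                dict(
                    classifier=e.classifier,
                    scaling=e.scaling,
                    accuracy_before=e.accuracy_before,
                    accuracy_after=e.accuracy_after,
                    accuracy_delta=e.accuracy_delta,
                    warning_count_before=e.warning_count_before,
                    warning_count_after=e.warning_count_after,
                    drift_count_before=e.drift_count_before,
                    drift_count_after=e.drift_count_after,
                    drift_free_after=e.drift_count_after == 0,
                )
            )
        return pd.DataFrame(rows)


def compare_before_after(before: dict, after: dict, correction: CorrectionSpec) -> ComparisonReport:
    """Pair per-(classifier, scaling) metrics from two pipeline runs.

    ``before`` and ``after`` map (classifier, scaling) keys to dicts with
    ``accuracy``, ``warning_count`` and ``drift_count``. Both runs must
    cover the same cells (identical splits/seeds/specs are the caller's
    responsibility and are enforced upstream by the pipeline manifest).
    """
    if set(before) != set(after):
        raise ValidationError(
            "mismatched run configurations: before/after cover different "
            f"(classifier, scaling) cells: {sorted(set(before) ^ set(after))}"
        )
    entries = []
    for key in sorted(before):
        b, a = before[key], after[key]
        entries.append(
            ComparisonEntry(
                classifier=key[0],
                scaling=key[1],
                accuracy_before=float(b["accuracy"]),
                accuracy_after=float(a["accuracy"]),
                warning_count_before=int(b["warning_count"]),
                warning_count_after=int(a["warning_count"]),
                drift_count_before=int(b["drift_count"]),
                drift_count_after=int(a["drift_count"]),
            )
        )
    return ComparisonReport(entries, correction)
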