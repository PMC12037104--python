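"""Synthetic cohorts with covariate-threshold concept drift.

The generator emulates the statistical structure of a two-class (sex)
metabolomic cohort in which a hidden covariate — by default age — changes
the feature→label relationship once it crosses a threshold:

* ~22 shared metabolites with positive baseline abundances (arbitrary
  units), Gaussian within-class noise;
* a per-metabolite sex effect (mean shift between classes in units of the
  within-class sd, alternating direction across metabolites);
* a right-skewed age distribution (young-adult-heavy healthy-volunteer
  cohort: 18 + Exp(scale 5.77) years, clipped to 18–75, median ~22) so the
  classifier predominantly learns the young-adult concept;
* past the ``true_threshold`` (default 26 y) the relationship on a subset of
  metabolites changes per ``drift_mode``: *flip* reverses the effect sign,
  *attenuate* shrinks it, *shift* adds a class-independent offset;
* missing values and occasional gross outliers at configurable rates.

Everything is reproducible from a single seed, and the emitted cohort uses
the same containers and CSV/TSV formats the harmonization stage reads, so
the full pipeline runs unmodified on simulated data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from metadrift.data import ClinicalTable, CohortDataset, MetaboliteMatrix, ValidationError
from metadrift.drift import ErrorStream
from metadrift.harmonize import split_dataset

DRIFT_MODES = ("flip", "attenuate", "shift")


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort."""

    n_samples: int = 500
    n_features: int = 22
    sex_effect: float = 1.0  # between-class mean shift, in within-class sd units
    drift_covariate: str = "age"
    covariate_range: tuple[float, float] = (18.0, 75.0)
    covariate_scale: float = 5.77  # exponential scale of the age distribution (years)
    covariate_distribution: str = "skewed_exponential"  # or "uniform"
    true_threshold: float = 26.0
    drift_mode: str = "flip"
    drift_magnitude: float = 1.0
    drift_feature_fraction: float = 0.5
    noise_sd: float = 1.0
    baseline_range: tuple[float, float] = (8.0, 12.0)  # per-feature abundance level
    missing_rate: float = 0.02
    outlier_rate: float = 0.005
    outlier_sd_multiplier: float = 5.0
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValidationError("n_features must be >= 1")
        for rate in (self.missing_rate, self.outlier_rate):
            if not 0.0 <= rate < 1.0:
                raise ValidationError("rates must lie in [0, 1)")
        lo, hi = self.covariate_range
        if not lo < self.true_threshold < hi:
            raise ValidationError("true_threshold must lie inside covariate_range")
        if self.drift_mode not in DRIFT_MODES:
            raise ValidationError(f"drift_mode must be one of {DRIFT_MODES}")
        if self.covariate_distribution not in ("skewed_exponential", "uniform"):
            raise ValidationError("covariate_distribution must be skewed_exponential or uniform")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    labels: list[str]
    covariate_values: list[float]
    covariate: str
    drifted_features: list[str]
    effect_signs: dict[str, float]
    true_threshold: float
    drift_mode: str
    n_features: int
    covariate_range: tuple[float, float]
    missing_cells: list[tuple[str, str]] = field(default_factory=list)
    outlier_cells: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2))


def _feature_ids(n: int) -> list[str]:
    # synthetic KEGG-like compound IDs, high-numbered to avoid real compounds
    return [f"C9{i:04d}" for i in range(1, n + 1)]


def _draw_covariate(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    lo, hi = config.covariate_range
    if config.covariate_distribution == "uniform":
        return rng.uniform(lo, hi, config.n_samples)
    values = lo + rng.exponential(config.covariate_scale, config.n_samples)
    return np.clip(values, lo, hi)


def generate_cohort(config: SimConfig) -> tuple[CohortDataset, GroundTruth]:
    """Simulate one cohort; reproducible for a fixed ``config.seed``."""
    last_error: Exception | None = None
    for attempt in range(10):
        try:
            return _generate_once(config, config.seed + 1_000_003 * attempt, attempt)
        except ValidationError as exc:  # infeasible draw (e.g. all-missing column)
            last_error = exc
    raise ValidationError(
        f"could not generate a feasible cohort after 10 attempts: {last_error}"
    )


def _generate_once(config: SimConfig, seed: int, attempt: int) -> tuple[CohortDataset, GroundTruth]:
    rng = np.random.default_rng(seed)
    n, p = config.n_samples, config.n_features
    features = _feature_ids(p)
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]

    covariate = _draw_covariate(rng, config)
    labels = np.where(rng.integers(0, 2, n) == 1, "female", "male")
    label_sign = np.where(labels == "female", 1.0, -1.0)
    beyond = covariate > config.true_threshold

    baseline = rng.uniform(*config.baseline_range, p)
    effect_signs = np.where(np.arange(p) % 2 == 0, 1.0, -1.0)
    n_drift = int(round(p * config.drift_feature_fraction))
    drifted = np.zeros(p, dtype=bool)
    drifted[rng.choice(p, size=n_drift, replace=False)] = True

    half_effect = 0.5 * config.sex_effect * config.noise_sd
    values = rng.normal(0.0, config.noise_sd, (n, p)) + baseline
    for j in range(p):
        effect = half_effect * effect_signs[j] * label_sign
        if drifted[j]:
            if config.drift_mode == "flip":
                # magnitude interpolates from unchanged (0) to full sign
                # reversal (1)
                effect = np.where(beyond, (1.0 - 2.0 * config.drift_magnitude) * effect, effect)
            elif config.drift_mode == "attenuate":
                effect = np.where(beyond, (1.0 - config.drift_magnitude) * effect, effect)
            else:  # shift: class-independent offset past the threshold
                offset = config.drift_magnitude * config.sex_effect * config.noise_sd
                effect = effect + np.where(beyond, offset, 0.0)
        values[:, j] += effect

    data = pd.DataFrame(values, index=sample_ids, columns=features)

    missing_cells: list[tuple[str, str]] = []
    if config.missing_rate > 0:
        # left-censored missingness: the lowest measurements of each
        # metabolite fall below the detection limit, which is what
        # half-minimum imputation is designed for
        limits = data.quantile(config.missing_rate, axis=0)
        mask = data.lt(limits, axis=1).to_numpy()
        if mask.all(axis=0).any():
            raise ValidationError("missing_rate left an all-missing feature column")
        data = data.mask(pd.DataFrame(mask, index=sample_ids, columns=features))
        rows, cols = np.nonzero(mask)
        missing_cells = [(sample_ids[r], features[c]) for r, c in zip(rows, cols)]

    outlier_cells: list[tuple[str, str]] = []
    if config.outlier_rate > 0:
        omask = rng.uniform(size=(n, p)) < config.outlier_rate
        omask &= ~data.isna().to_numpy()
        bump = config.outlier_sd_multiplier * config.noise_sd
        signs = np.where(rng.uniform(size=(n, p)) < 0.5, -1.0, 1.0)
        data = data + pd.DataFrame(omask * signs * bump, index=sample_ids, columns=features)
        rows, cols = np.nonzero(omask)
        outlier_cells = [(sample_ids[r], features[c]) for r, c in zip(rows, cols)]

    clinical = ClinicalTable(
        pd.DataFrame(
            {"sex": labels, config.drift_covariate: covariate},
            index=sample_ids,
        ),
        target="sex",
    )
    dataset = CohortDataset(MetaboliteMatrix(data), clinical)
    dataset = split_dataset(dataset, config.test_fraction, seed=config.seed)

    truth = GroundTruth(
        labels=labels.tolist(),
        covariate_values=covariate.tolist(),
        covariate=config.drift_covariate,
        drifted_features=[f for f, d in zip(features, drifted) if d],
        effect_signs={f: float(s) for f, s in zip(features, effect_signs)},
        true_threshold=config.true_threshold,
        drift_mode=config.drift_mode,
        n_features=p,
        covariate_range=tuple(config.covariate_range),
        missing_cells=missing_cells,
        outlier_cells=outlier_cells,
    )
    return dataset, truth


def generate_error_stream(
    length: int, change_points: list[tuple[int, float]], seed: int = 0
) -> ErrorStream:
    """Piecewise-Bernoulli binary stream for detector tests.

    ``change_points`` lists (start_index, error_rate) pairs with strictly
    ascending indices; the rate before the first listed index is 0.
    """
    rates = np.zeros(length)
    previous = -1
    for index, rate in change_points:
        if index <= previous:
            raise ValidationError("change point indices must be strictly ascending")
        if not 0.0 <= rate <= 1.0:
            raise ValidationError("error rates must lie in [0, 1]")
        previous = index
        rates[index:] = rate
    rng = np.random.default_rng(seed)
    errors = (rng.uniform(size=length) < rates).astype(int)
    ids = [f"s{i:05d}" for i in range(length)]
    return ErrorStream(ids, errors, "dataset_order")
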