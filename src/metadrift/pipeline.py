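"""End-to-end orchestration: conventional prediction, drift analysis, correction.

``run_pipeline`` executes the three sections of the workflow:

A. harmonize the cohort, scale it (parameters fitted on the training split),
   train and evaluate each classifier family — the conventional
   metabolomics prediction baseline;
B. build covariate-ordered out-of-fold error streams, run DDM and EDDM,
   associate confirmed events with candidate covariates, nominate the
   confounding factor and derive its threshold;
C. correct the models (segmentation or stratified scaling at the derived
   threshold), retrain, re-run detection, and report paired before/after
   accuracies and drift counts.

The error streams of Section B are replicated over several cross-validation
shuffles; event counts are summarized as the median over replicates and the
drift onset as the median of per-replicate maximum-likelihood changepoints,
which removes detector latency from the threshold estimate. Only *confirmed*
events (see :func:`metadrift.drift.confirmed_events`) enter nomination and
the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from metadrift import __version__
from metadrift.classify import (
    FittedModel,
    ModelSpec,
    out_of_fold_predictions,
    train_model,
)
from metadrift.confounder import (
    CovariateAssociation,
    associate_covariate,
    derive_threshold,
    estimate_change_index,
    rank_covariates,
)
from metadrift.correct import (
    ComparisonReport,
    CorrectionSpec,
    add_confounder_feature,
    binarize_covariate,
    compare_before_after,
    segment_by_threshold,
    stratified_scale,
)
from metadrift.data import (
    ClinicalTable,
    CohortDataset,
    MetaboliteMatrix,
    ValidationError,
    read_mapping,
)
from metadrift.drift import (
    DDMConfig,
    DetectorConfig,
    EDDMConfig,
    build_error_stream,
    confirmed_events,
    ddm_detect,
    eddm_detect,
    events_table,
)
from metadrift.harmonize import impute_half_min, map_identifiers, remove_outliers, split_dataset
from metadrift.scaling import ScalingSpec, apply_scaler, fit_scaler
from metadrift.simulate import SimConfig, generate_cohort

logger = logging.getLogger("metadrift")


@dataclass
class InputPaths:
    abundance: str
    clinical: str
    mapping: str | None = None
    target: str = "sex"


@dataclass
class HarmonizeBlock:
    outlier_policy: str = "replace"  # "replace" (blank + re-impute) or "report"
    test_fraction: float = 0.2


@dataclass
class ScalingBlock:
    methods: list[str] = field(default_factory=lambda: ["autoscaling"])
    fit_on: str = "train"
    epsilon: float = 1e-12
    power_exponent: float = 0.5


@dataclass
class ClassifyBlock:
    families: list[str] = field(default_factory=lambda: ["knn"])
    cv_folds: int = 10
    epochs: int = 200
    learning_rate: float = 1e-3


@dataclass
class DriftBlock:
    detectors: list[str] = field(default_factory=lambda: ["ddm", "eddm"])
    stream: str = "oof"  # "oof" (cross-validated, default), "test", "all"
    replicates: int = 8
    ddm: DDMConfig = field(default_factory=DDMConfig)
    eddm: EDDMConfig = field(default_factory=EDDMConfig)


@dataclass
class ConfounderBlock:
    candidates: list[str] | None = None  # None = every non-target covariate
    threshold_rule: str = "mean_of_warnings"
    refine_onset: bool = True


@dataclass
class CorrectionBlock:
    strategy: str = "segmentation"
    covariate: str | None = None  # None = accept the nominated covariate
    threshold: float | None = None  # None = derived threshold
    add_indicator: bool = True
    refit: bool = True


@dataclass
class RunConfig:
    """Full run configuration; exactly one of input/simulate must be set."""

    input: InputPaths | None = None
    simulate: SimConfig | None = None
    harmonize: HarmonizeBlock = field(default_factory=HarmonizeBlock)
    scaling: ScalingBlock = field(default_factory=ScalingBlock)
    classify: ClassifyBlock = field(default_factory=ClassifyBlock)
    drift: DriftBlock = field(default_factory=DriftBlock)
    confounder: ConfounderBlock = field(default_factory=ConfounderBlock)
    correction: CorrectionBlock = field(default_factory=CorrectionBlock)
    outdir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input is None) == (self.simulate is None):
            raise ValidationError(
                "exactly one of 'input' and 'simulate' must be configured"
            )

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        kwargs: dict = {}
        if "input" in raw and raw["input"] is not None:
            kwargs["input"] = InputPaths(**raw.pop("input"))
        else:
            raw.pop("input", None)
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw.pop("simulate"))
            for key in ("covariate_range", "baseline_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["simulate"] = SimConfig(**sim)
        else:
            raw.pop("simulate", None)
        blocks = {
            "harmonize": HarmonizeBlock,
            "scaling": ScalingBlock,
            "classify": ClassifyBlock,
            "confounder": ConfounderBlock,
            "correction": CorrectionBlock,
        }
        for name, cls_ in blocks.items():
            if name in raw and raw[name] is not None:
                kwargs[name] = cls_(**raw.pop(name))
            else:
                raw.pop(name, None)
        if "drift" in raw and raw["drift"] is not None:
            block = dict(raw.pop("drift"))
            if "ddm" in block:
                block["ddm"] = DDMConfig(**block["ddm"])
            if "eddm" in block:
                block["eddm"] = EDDMConfig(**block["eddm"])
            kwargs["drift"] = DriftBlock(**block)
        else:
            raw.pop("drift", None)
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CellAnalysis:
    """Section B output for one (classifier, scaling) cell."""

    family: str
    scaling: str
    oof_accuracy: float
    warning_count: int
    drift_count: int
    eddm_warning_count: int
    eddm_drift_count: int
    associations: dict[str, CovariateAssociation]
    onsets: dict[str, list[float]]  # covariate -> per-replicate refined onset values
    confirming_replicates: dict[str, int]


@dataclass
class PipelineResult:
    config: RunConfig
    dataset: CohortDataset
    metrics: pd.DataFrame
    analyses: list[CellAnalysis]
    nominated_covariate: str | None
    derived_threshold: float | None
    report: ComparisonReport | None
    events: pd.DataFrame
    ground_truth: object | None = None


def _sub_seed(seed: int, *offsets: int) -> int:
    value = seed
    for off in offsets:
        value = (value * 1_000 + off) % (2**31 - 1)
    return value


def load_cohort(config: RunConfig) -> tuple[CohortDataset, object | None]:
    """Stage 1: read or simulate, then clean and split."""
    if config.simulate is not None:
        dataset, truth = generate_cohort(config.simulate)
    else:
        paths = config.input
        matrix = MetaboliteMatrix.read_table(paths.abundance)
        clinical = ClinicalTable.read_table(paths.clinical, target=paths.target)
        if paths.mapping:
            matrix, report = map_identifiers(matrix, read_mapping(paths.mapping))
            if report.dropped:
                logger.info("dropped %d unmapped features: %s", len(report.dropped), report.dropped)
        clinical = clinical.select_samples(matrix.sample_ids)
        dataset = CohortDataset(matrix, clinical)
        truth = None
    # cleaning: half-minimum imputation, then the configured outlier policy
    matrix = impute_half_min(dataset.matrix)
    groups = dataset.clinical.labels
    if config.harmonize.outlier_policy == "replace":
        matrix, outliers = remove_outliers(matrix, groups)
        if len(outliers):
            logger.info("re-imputed %d outlying measurements", len(outliers))
    dataset = dataset.with_matrix(matrix)
    if set(dataset.split.unique()) == {"unassigned"}:
        dataset = split_dataset(dataset, config.harmonize.test_fraction, seed=config.seed)
    return dataset, truth


def _scaled_dataset(dataset: CohortDataset, method: str, block: ScalingBlock) -> CohortDataset:
    spec = ScalingSpec(method, block.epsilon, block.power_exponent)
    fit_ids = dataset.sample_ids if block.fit_on == "all" else dataset.samples_in(block.fit_on)
    params = fit_scaler(dataset.matrix.select_samples(fit_ids), spec)
    return dataset.with_matrix(apply_scaler(dataset.matrix, params, spec))


def run_section_a(
    dataset: CohortDataset, config: RunConfig
) -> tuple[pd.DataFrame, dict[tuple[str, str], FittedModel], dict[str, CohortDataset]]:
    """Train/evaluate every family on every scaling; Table-2-style metrics."""
    rows = []
    models: dict[tuple[str, str], FittedModel] = {}
    scaled: dict[str, CohortDataset] = {}
    for method in config.scaling.methods:
        scaled[method] = _scaled_dataset(dataset, method, config.scaling)
        for family in config.classify.families:
            spec = ModelSpec(
                family=family,
                seed=_sub_seed(config.seed, 1),
                cv_folds=config.classify.cv_folds,
                epochs=config.classify.epochs,
                learning_rate=config.classify.learning_rate,
            )
            model = train_model(scaled[method], spec)
            models[(family, method)] = model
            for split in ("train", "test"):
                from metadrift.classify import evaluate

                result = evaluate(model, scaled[method], split)
                rows.append(
                    dict(
                        scaling=method,
                        family=family,
                        split=split,
                        accuracy=result.accuracy,
                        seed=config.seed,
                    )
                )
    return pd.DataFrame(rows), models, scaled


def _replicate_streams(
    scaled: CohortDataset, model: FittedModel, config: RunConfig
):
    """Per-replicate PredictionResults for Section B streams."""
    block = config.drift
    results = []
    if block.stream in ("test", "all"):
        from metadrift.classify import evaluate

        results.append(evaluate(model, scaled, block.stream))
        return results
    for rep in range(block.replicates):
        results.append(
            out_of_fold_predictions(
                scaled, model.spec, model=model, n_folds=10,
                seed=_sub_seed(config.seed, 7, rep),
            )
        )
    return results


def analyze_cell(
    scaled: CohortDataset,
    model: FittedModel,
    family: str,
    method: str,
    config: RunConfig,
    candidates: list[str],
) -> tuple[CellAnalysis, pd.DataFrame]:
    """Section B for one (family, scaling) cell."""
    det_config = DetectorConfig(config.drift.ddm, config.drift.eddm)
    results = _replicate_streams(scaled, model, config)
    clinical = scaled.clinical

    per_rep_counts = {"ddm_warn": [], "ddm_drift": [], "eddm_warn": [], "eddm_drift": []}
    onsets: dict[str, list[float]] = {c: [] for c in candidates}
    confirming: dict[str, int] = {c: 0 for c in candidates}
    associations: dict[str, CovariateAssociation] = {}
    events_rows = []

    for rep, result in enumerate(results):
        for covariate in candidates:
            stream = build_error_stream(result, clinical, covariate)
            ddm_events = confirmed_events(
                ddm_detect(stream, det_config)
            ) if "ddm" in config.drift.detectors else []
            eddm_events = eddm_detect(stream, det_config) if "eddm" in config.drift.detectors else []
            if rep == 0:
                associations[covariate] = associate_covariate(
                    ddm_events + eddm_events, stream, clinical, covariate
                )
                table = events_table(ddm_events + eddm_events, stream, clinical)
                if len(table):
                    table.insert(0, "scaling", method)
                    table.insert(0, "classifier", family)
                    events_rows.append(table)
            ddm_drifts = [e for e in ddm_events if e.level == "drift"]
            if covariate == candidates[0]:
                per_rep_counts["ddm_warn"].append(
                    sum(e.level == "warning" for e in ddm_events)
                )
                per_rep_counts["ddm_drift"].append(len(ddm_drifts))
                per_rep_counts["eddm_warn"].append(
                    sum(e.level == "warning" for e in eddm_events)
                )
                per_rep_counts["eddm_drift"].append(
                    sum(e.level == "drift" for e in eddm_events)
                )
            if ddm_drifts:
                confirming[covariate] += 1
                if config.confounder.refine_onset:
                    onset = estimate_change_index(stream.errors)
                    if onset is not None:
                        values = clinical.covariate(covariate)
                        onsets[covariate].append(float(values.loc[stream.sample_ids[onset]]))

    def med(key):
        return int(np.median(per_rep_counts[key])) if per_rep_counts[key] else 0

    analysis = CellAnalysis(
        family=family,
        scaling=method,
        oof_accuracy=float(np.mean([r.accuracy for r in results])),
        warning_count=med("ddm_warn"),
        drift_count=med("ddm_drift"),
        eddm_warning_count=med("eddm_warn"),
        eddm_drift_count=med("eddm_drift"),
        associations=associations,
        onsets=onsets,
        confirming_replicates=confirming,
    )
    events = pd.concat(events_rows, ignore_index=True) if events_rows else pd.DataFrame()
    return analysis, events


def nominate(
    analyses: list[CellAnalysis], config: RunConfig
) -> tuple[str | None, float | None]:
    """Pick the confounding covariate and its threshold across all cells.

    The covariate confirmed by the most replicate streams wins (ties broken
    by tighter warning clustering). The threshold is the median refined
    onset when available, otherwise the configured association rule.
    """
    total_confirming: dict[str, int] = {}
    pooled_onsets: dict[str, list[float]] = {}
    for cell in analyses:
        for cov, count in cell.confirming_replicates.items():
            total_confirming[cov] = total_confirming.get(cov, 0) + count
            pooled_onsets.setdefault(cov, []).extend(cell.onsets.get(cov, []))
    if not total_confirming or max(total_confirming.values()) == 0:
        logger.info("no confirmed drift in any replicate; no confounder nominated")
        return None, None
    best_count = max(total_confirming.values())
    tied = [c for c, n in total_confirming.items() if n == best_count]
    if len(tied) > 1:
        ranked = rank_covariates(
            [cell.associations[c] for cell in analyses[:1] for c in tied]
        )
        covariate = ranked[0].covariate
    else:
        covariate = tied[0]
    if config.confounder.refine_onset and pooled_onsets.get(covariate):
        threshold = float(np.median(pooled_onsets[covariate]))
    else:
        assoc = analyses[0].associations[covariate]
        threshold = derive_threshold(assoc, config.confounder.threshold_rule)
    return covariate, threshold


def correct_cell(
    dataset: CohortDataset,
    scaled: CohortDataset,
    model: FittedModel,
    family: str,
    method: str,
    config: RunConfig,
    correction: CorrectionSpec,
) -> dict:
    """Section C for one cell: corrected retraining + re-detection.

    With ``refit`` (the default) hyperparameters are re-selected on the
    corrected training data; otherwise the before-run's selection is reused.
    """
    det_config = DetectorConfig(config.drift.ddm, config.drift.eddm)
    clinical = dataset.clinical
    strata = binarize_covariate(clinical, correction.covariate, correction.threshold)
    spec = ModelSpec(
        family=family,
        seed=_sub_seed(config.seed, 1),
        cv_folds=config.classify.cv_folds,
        epochs=config.classify.epochs,
        learning_rate=config.classify.learning_rate,
    )

    # corrected datasets (and, when refitting, hyperparameter selection) are
    # fixed once; the replicates vary only the cross-validation shuffle
    if correction.strategy == "segmentation":
        strata_ds = segment_by_threshold(dataset, correction)
        prepared = []
        for stratum in strata_ds:
            stratum_scaled = _scaled_dataset(stratum, method, config.scaling)
            sub_model = train_model(stratum_scaled, spec) if correction.refit else model
            prepared.append((stratum_scaled, sub_model))
    else:
        scaling_spec = ScalingSpec(method, config.scaling.epsilon, config.scaling.power_exponent)
        train_ids = dataset.samples_in("train") or dataset.sample_ids
        corrected = stratified_scale(dataset.matrix, strata, scaling_spec, train_ids)
        if correction.add_indicator:
            corrected = add_confounder_feature(corrected, strata)
        corrected_ds = dataset.with_matrix(corrected)
        sub_model = train_model(corrected_ds, spec) if correction.refit else model
        prepared = [(corrected_ds, sub_model)]

    accuracies, warn_counts, drift_counts = [], [], []
    for rep in range(config.drift.replicates):
        rep_seed = _sub_seed(config.seed, 7, rep)
        parts = [
            out_of_fold_predictions(ds, spec, model=mdl, n_folds=10, seed=rep_seed)
            for ds, mdl in prepared
        ]
        if len(parts) == 1:
            result = parts[0]
        else:
            from metadrift.classify import PredictionResult

            ids = [sid for part in parts for sid in part.sample_ids]
            predicted = np.concatenate([np.asarray(p.predicted) for p in parts])
            true = np.concatenate([np.asarray(p.true) for p in parts])
            result = PredictionResult(ids, predicted, true, float(np.mean(predicted == true)))
        accuracies.append(result.accuracy)
        stream = build_error_stream(result, clinical, correction.covariate)
        events = confirmed_events(ddm_detect(stream, det_config))
        warn_counts.append(sum(e.level == "warning" for e in events))
        drift_counts.append(sum(e.level == "drift" for e in events))

    return dict(
        accuracy=float(np.mean(accuracies)),
        warning_count=int(np.median(warn_counts)),
        drift_count=int(np.median(drift_counts)),
    )


def run_pipeline(config: RunConfig, confirm=None) -> PipelineResult:
    """Execute Sections A, B and C; write artifacts when an outdir is set.

    ``confirm`` is the semi-automated expert gate: a callable receiving the
    nominated covariate and threshold and returning True to proceed with the
    correction. None accepts automatically (the --auto-accept behavior).
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    dataset, truth = load_cohort(config)
    metrics, models, scaled_by_method = run_section_a(dataset, config)
    logger.info("Section A complete: %d cells", len(models))

    candidates = config.confounder.candidates
    if candidates is None:
        candidates = dataset.clinical.covariate_names
    if not candidates:
        raise ValidationError("no candidate covariates available for drift analysis")

    analyses = []
    events_frames = []
    for (family, method), model in models.items():
        analysis, events = analyze_cell(
            scaled_by_method[method], model, family, method, config, candidates
        )
        analyses.append(analysis)
        if len(events):
            events_frames.append(events)
    events = pd.concat(events_frames, ignore_index=True) if events_frames else pd.DataFrame()

    covariate, threshold = nominate(analyses, config)
    if config.correction.covariate is not None:
        covariate = config.correction.covariate
    if config.correction.threshold is not None:
        threshold = config.correction.threshold
    logger.info("nominated confounder: %s at threshold %s", covariate, threshold)

    report = None
    if covariate is not None and threshold is not None:
        if confirm is not None and not confirm(covariate, threshold):
            logger.info("expert declined the nomination; skipping Section C")
        else:
            correction = CorrectionSpec(
                strategy=config.correction.strategy,
                covariate=covariate,
                threshold=float(threshold),
                scaling=ScalingSpec(
                    config.scaling.methods[0], config.scaling.epsilon,
                    config.scaling.power_exponent,
                ),
                add_indicator=config.correction.add_indicator,
                refit=config.correction.refit,
            )
            before, after = {}, {}
            for cell in analyses:
                before[(cell.family, cell.scaling)] = dict(
                    accuracy=cell.oof_accuracy,
                    warning_count=cell.warning_count,
                    drift_count=cell.drift_count,
                )
            for (family, method), model in models.items():
                after[(family, method)] = correct_cell(
                    dataset, scaled_by_method[method], model, family, method,
                    config, correction,
                )
            report = compare_before_after(before, after, correction)

    result = PipelineResult(
        config=config,
        dataset=dataset,
        metrics=metrics,
        analyses=analyses,
        nominated_covariate=covariate,
        derived_threshold=threshold,
        report=report,
        events=events,
        ground_truth=truth,
    )
    if outdir:
        write_artifacts(result, outdir)
    return result


def write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.dataset.matrix.write_table(outdir / "harmonized.tsv")
    result.dataset.clinical.write_table(outdir / "clinical.tsv")
    result.dataset.split.to_csv(outdir / "split.tsv", sep="\t", header=["split"])
    result.metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    if len(result.events):
        result.events.to_csv(outdir / "events.tsv", sep="\t", index=False)
    association = {
        "nominated_covariate": result.nominated_covariate,
        "derived_threshold": result.derived_threshold,
        "cells": [
            {
                "classifier": cell.family,
                "scaling": cell.scaling,
                "oof_accuracy": cell.oof_accuracy,
                "ddm": {"warnings": cell.warning_count, "drifts": cell.drift_count},
                "eddm": {
                    "warnings": cell.eddm_warning_count,
                    "drifts": cell.eddm_drift_count,
                },
                "confirming_replicates": cell.confirming_replicates,
                "associations": {
                    cov: assoc.summary() for cov, assoc in cell.associations.items()
                },
            }
            for cell in result.analyses
        ],
    }
    (outdir / "association.json").write_text(json.dumps(association, indent=2))
    if result.report is not None:
        frame = result.report.to_frame()
        frame.to_csv(outdir / "comparison.tsv", sep="\t", index=False)
        (outdir / "comparison.json").write_text(frame.to_json(orient="records", indent=2))
    if result.ground_truth is not None:
        result.ground_truth.to_json(outdir / "ground_truth.json")
    manifest = {
        "metadrift_version": __version__,
        "seed": result.config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(result.config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": result.config.to_dict(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
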