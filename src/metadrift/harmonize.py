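"""Dataset unification and cleaning for cross-study metabolomics.

The harmonization steps mirror standard practice for merging quantified
metabolite tables from different studies: rename free-text metabolite names
to KEGG compound IDs, restrict every table to the shared feature set, fill
missing abundances with half the per-metabolite minimum, flag measurements
beyond two standard deviations of their condition-group mean, and produce a
stratified train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from metadrift.data import (
    KEGG_ID_PATTERN,
    ClinicalTable,
    CohortDataset,
    MetaboliteMatrix,
    ValidationError,
)


class AmbiguousMappingError(ValidationError):
    """Two input features map to the same KEGG compound ID."""


@dataclass
class MappingReport:
    renamed: dict[str, str] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)


def map_identifiers(
    matrix: MetaboliteMatrix, mapping: dict[str, str]
) -> tuple[MetaboliteMatrix, MappingReport]:
    """Rename features to KEGG compound IDs; drop features with no mapping.

    Features already carrying their final KEGG ID must appear in the mapping
    (possibly mapped to themselves) to be retained. A collision — two input
    features mapped to the same KEGG ID — raises, because silently merging
    abundances from distinct assays would fabricate data.
    """
    for name, kegg in mapping.items():
        if not KEGG_ID_PATTERN.match(str(kegg)):
            raise ValidationError(
                f"malformed KEGG compound ID {kegg!r} for {name!r} "
                "(expected 'C' followed by 5 digits)"
            )
    report = MappingReport()
    targets: dict[str, list[str]] = {}
    keep: list[str] = []
    for feat in matrix.feature_ids:
        if feat in mapping:
            kegg = mapping[feat]
            targets.setdefault(kegg, []).append(feat)
            keep.append(feat)
            report.renamed[feat] = kegg
        else:
            report.dropped.append(feat)
    collisions = {k: v for k, v in targets.items() if len(v) > 1}
    if collisions:
        desc = "; ".join(f"{k} <- {v}" for k, v in sorted(collisions.items()))
        raise AmbiguousMappingError(f"ambiguous mapping, colliding features: {desc}")
    out = matrix.data[keep].rename(columns=report.renamed)
    return MetaboliteMatrix(out), report


def intersect_features(matrices: list[MetaboliteMatrix]) -> list[MetaboliteMatrix]:
    """Restrict every matrix to the shared feature set, lexicographic order."""
    if len(matrices) < 2:
        raise ValidationError("need at least two matrices to intersect")
    shared = set(matrices[0].feature_ids)
    for m in matrices[1:]:
        shared &= set(m.feature_ids)
    if not shared:
        counts = ", ".join(str(m.n_features) for m in matrices)
        raise ValidationError(
            f"empty feature intersection (per-matrix feature counts: {counts})"
        )
    order = sorted(shared)
    return [MetaboliteMatrix(m.data[order].copy()) for m in matrices]


def impute_half_min(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Fill each missing entry with half the column's minimum observed value.

    Idempotent: observed entries are carried over bit-identically, and a
    matrix without missing values is returned unchanged.
    """
    data = matrix.data.copy()
    for col in data.columns:
        column = data[col]
        if column.isna().all():
            raise ValidationError(f"feature {col!r} has no observed values to impute from")
        if column.isna().any():
            data[col] = column.fillna(0.5 * column.min())
    return MetaboliteMatrix(data)


def flag_outliers(matrix: MetaboliteMatrix, groups: pd.Series) -> pd.DataFrame:
    """Flag entries beyond 2 sample standard deviations of their group mean.

    ``groups`` assigns each sample a condition label; mean and sd (n-1
    denominator) are computed per condition per compound. The strict
    inequality means constant columns (sd = 0) flag nothing. Returns a
    boolean mask aligned with the matrix; the masking policy (report only,
    or blank and re-impute) is the caller's.
    """
    if matrix.missing_mask.to_numpy().any():
        raise ValidationError("flag_outliers requires a complete (imputed) matrix")
    groups = groups.loc[matrix.data.index]
    mask = pd.DataFrame(False, index=matrix.data.index, columns=matrix.data.columns)
    for label, idx in groups.groupby(groups).groups.items():
        block = matrix.data.loc[idx]
        if len(block) < 2:
            raise ValidationError(
                f"condition group {label!r} has a single sample; sd is undefined"
            )
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        mask.loc[idx] = (block - mean).abs() > 2.0 * sd
    return mask


def outlier_report(matrix: MetaboliteMatrix, groups: pd.Series, mask: pd.DataFrame) -> pd.DataFrame:
    """Long-format report of flagged cells (sample, feature, value, group stats)."""
    rows = []
    groups = groups.loc[matrix.data.index]
    stats: dict = {}
    for label, idx in groups.groupby(groups).groups.items():
        block = matrix.data.loc[idx]
        stats[label] = (block.mean(axis=0), block.std(axis=0, ddof=1))
    for sample in matrix.data.index:
        flagged = mask.loc[sample]
        for feat in matrix.data.columns[flagged]:
            mean, sd = stats[groups.loc[sample]]
            rows.append(
                dict(
                    sample_id=sample,
                    feature_id=feat,
                    value=matrix.data.at[sample, feat],
                    group_mean=mean[feat],
                    group_sd=sd[feat],
                )
            )
    return pd.DataFrame(rows, columns=["sample_id", "feature_id", "value", "group_mean", "group_sd"])


def remove_outliers(
    matrix: MetaboliteMatrix, groups: pd.Series
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Default outlier policy: blank flagged cells and re-impute once.

    Keeps the matrix shape intact for downstream classifiers. The single
    re-imputation pass is deliberate — iterating flag/impute to a fixed
    point would erode genuine tails.
    """
    mask = flag_outliers(matrix, groups)
    report = outlier_report(matrix, groups, mask)
    if not mask.to_numpy().any():
        return matrix, report
    blanked = matrix.data.mask(mask)
    return impute_half_min(MetaboliteMatrix(blanked)), report


def split_dataset(dataset: CohortDataset, test_fraction: float, seed: int = 42) -> CohortDataset:
    """Assign a stratified train/test split, reproducible for a fixed seed."""
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must lie strictly between 0 and 1")
    labels = dataset.clinical.labels
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValidationError("need at least two target classes to split")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValidationError(
            f"classes {small} have fewer than 2 samples; cannot place one in "
            "each of train and test"
        )
    ids = np.asarray(dataset.sample_ids)
    train_ids, test_ids = train_test_split(
        ids,
        test_size=test_fraction,
        stratify=labels.to_numpy(),
        random_state=seed,
        shuffle=True,
    )
    split = pd.Series("train", index=dataset.matrix.data.index, name="split")
    split.loc[test_ids] = "test"
    return CohortDataset(dataset.matrix, dataset.clinical, split)
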