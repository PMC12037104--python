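"""Core tabular containers: abundance matrices, clinical tables, cohorts.

All containers are thin, validated wrappers around :class:`pandas.DataFrame`.
Missing abundances are represented as NaN; the boolean missingness mask is
derived, never stored separately, so the two can't fall out of sync.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

KEGG_ID_PATTERN = re.compile(r"^C\d{5}$")

SPLIT_TAGS = ("train", "test", "validation", "unassigned")


class ValidationError(ValueError):
    """Raised when a container or mapping violates its invariants."""


def _check_unique(values, kind: str) -> None:
    values = pd.Index(values)
    if values.has_duplicates:
        dupes = values[values.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated {kind}: {dupes}")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


@dataclass
class MetaboliteMatrix:
    """Sample x metabolite abundance table.

    Parameters
    ----------
    data:
        DataFrame with sample IDs as index and feature IDs (typically KEGG
        compound IDs such as ``"C00300"``) as columns. NaN marks a missing
        measurement.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        _check_unique(self.data.index, "sample IDs")
        _check_unique(self.data.columns, "feature IDs")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def feature_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(self.data.copy())

    def select_samples(self, sample_ids) -> "MetaboliteMatrix":
        return MetaboliteMatrix(self.data.loc[list(sample_ids)].copy())

    @classmethod
    def read_table(cls, path) -> "MetaboliteMatrix":
        """Read an abundance CSV/TSV (first column = sample ID)."""
        path = Path(path)
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        return cls(df)

    def write_table(self, path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep=_sep_for(path), index_label="sample_id")


@dataclass
class ClinicalTable:
    """Per-sample target label plus clinical covariates (age, BMI, ...)."""

    data: pd.DataFrame
    target: str = "target"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data.index = self.data.index.astype(str)
        _check_unique(self.data.index, "sample IDs")
        if self.target not in self.data.columns:
            raise ValidationError(
                f"target column {self.target!r} not in clinical table "
                f"(columns: {self.data.columns.tolist()})"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def labels(self) -> pd.Series:
        return self.data[self.target]

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c != self.target]

    def covariate(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"unknown covariate {name!r}; have {self.covariate_names}")
        return self.data[name]

    def select_samples(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy(), target=self.target)

    @classmethod
    def read_table(cls, path, target: str = "target") -> "ClinicalTable":
        path = Path(path)
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        return cls(df, target=target)

    def write_table(self, path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep=_sep_for(path), index_label="sample_id")


@dataclass
class CohortDataset:
    """A paired abundance matrix and clinical table with a split assignment."""

    matrix: MetaboliteMatrix
    clinical: ClinicalTable
    split: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.matrix.sample_ids != self.clinical.sample_ids:
            raise ValidationError(
                "matrix and clinical table must cover the same samples in the "
                "same order"
            )
        if self.split is None:
            self.split = pd.Series(
                "unassigned", index=self.matrix.data.index, name="split"
            )
        self.split = self.split.astype(str)
        self.split.index = self.split.index.astype(str)
        if list(self.split.index) != self.matrix.sample_ids:
            raise ValidationError("split assignment must align with sample IDs")
        bad = set(self.split.unique()) - set(SPLIT_TAGS)
        if bad:
            raise ValidationError(f"unknown split tags: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.sample_ids

    def samples_in(self, tag: str) -> list[str]:
        return self.split.index[self.split == tag].tolist()

    def subset(self, sample_ids) -> "CohortDataset":
        ids = list(sample_ids)
        return CohortDataset(
            self.matrix.select_samples(ids),
            self.clinical.select_samples(ids),
            self.split.loc[ids].copy(),
        )

    def with_matrix(self, matrix: MetaboliteMatrix) -> "CohortDataset":
        return CohortDataset(matrix, self.clinical, self.split.copy())


def read_mapping(path) -> dict[str, str]:
    """Read a metabolite-name -> KEGG compound ID mapping CSV/TSV.

    Expects two columns (name, kegg_id); extra columns are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValidationError("mapping table needs columns (name, kegg_id)")
    name_col, kegg_col = df.columns[:2]
    return dict(zip(df[name_col].astype(str), df[kegg_col].astype(str)))
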