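import numpy as np
import pandas as pd
import pytest

from metadrift.data import ClinicalTable, CohortDataset, MetaboliteMatrix


def make_matrix(values, sample_ids=None, feature_ids=None) -> MetaboliteMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    feature_ids = feature_ids or [f"C{i:05d}" for i in range(1, p + 1)]
    return MetaboliteMatrix(pd.DataFrame(values, index=sample_ids, columns=feature_ids))


def make_cohort(values, labels, covariates=None, split=None) -> CohortDataset:
    matrix = make_matrix(values)
    frame = pd.DataFrame({"sex": list(labels)}, index=matrix.data.index)
    for name, vals in (covariates or {}).items():
        frame[name] = list(vals)
    clinical = ClinicalTable(frame, target="sex")
    split_series = None
    if split is not None:
        split_series = pd.Series(list(split), index=matrix.data.index, name="split")
    return CohortDataset(matrix, clinical, split_series)


@pytest.fixture
def separable_cohort():
    """Linearly separable two-feature toy: class means +-3, sd 0.1, n=40."""
    rng = np.random.default_rng(7)
    n_half = 20
    X = np.vstack(
        [
            rng.normal(-3.0, 0.1, (n_half, 2)),
            rng.normal(3.0, 0.1, (n_half, 2)),
        ]
    )
    labels = ["male"] * n_half + ["female"] * n_half
    split = ["train"] * n_half + ["train"] * n_half
    return make_cohort(X, labels, split=split)
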