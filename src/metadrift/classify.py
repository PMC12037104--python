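"""Phenotype classifiers over scaled abundance matrices.

Five model families are supported at contract level — k-nearest neighbours,
ridge classifier, thresholded support-vector regression, random forest, and
a feed-forward neural network trained with an adaptive-moment optimizer.
Hyperparameters are chosen by stratified k-fold cross-validated accuracy
over small pinned grids; every family is seeded for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import RidgeClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVR
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, validate_data

from metadrift.data import CohortDataset, ValidationError

FAMILIES = ("knn", "ridge", "svr_threshold", "random_forest", "dnn")

#: pinned default search grids, deliberately small; override via ModelSpec
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "knn": {"n_neighbors": [3, 5, 7]},
    "ridge": {"alpha": [0.1, 1.0, 10.0]},
    "svr_threshold": {"C": [1.0]},
    "random_forest": {"n_estimators": [200]},
    "dnn": {"hidden_layer_sizes": [(32, 16)]},
}


class ThresholdedSVRClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier from a support-vector regression on 0/1 labels.

    The regressor is fitted against the classes encoded 0/1 (in ``classes_``
    order) and a sample is assigned the positive class iff the regression
    output is at least 0.5 — equivalently, the sign rule applied to
    ``decision_function = prediction - 0.5``.
    """

    def __init__(self, C: float = 1.0, kernel: str = "rbf", gamma: str = "scale"):
        self.C = C
        self.kernel = kernel
        self.gamma = gamma

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) != 2:
            raise ValidationError("ThresholdedSVRClassifier requires exactly two classes")
        encoded = (y == self.classes_[1]).astype(float)
        self.svr_ = SVR(C=self.C, kernel=self.kernel, gamma=self.gamma)
        self.svr_.fit(X, encoded)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "svr_")
        X = validate_data(self, X, reset=False)
        return self.svr_.predict(X) - 0.5

    def predict(self, X):
        return self.classes_[(self.decision_function(X) >= 0).astype(int)]


@dataclass
class ModelSpec:
    """Family choice plus training configuration."""

    family: str = "knn"
    hyperparameters: dict = field(default_factory=dict)
    grid: dict | None = None
    seed: int = 0
    cv_folds: int = 10
    epochs: int = 200
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be at least 2")


def build_estimator(spec: ModelSpec) -> BaseEstimator:
    """Bare (unfitted) estimator for a family, seeded where stochastic."""
    hp = dict(spec.hyperparameters)
    if spec.family == "knn":
        return KNeighborsClassifier(**{"n_neighbors": 5, **hp})
    if spec.family == "ridge":
        return RidgeClassifier(**{"alpha": 1.0, **hp})
    if spec.family == "svr_threshold":
        return ThresholdedSVRClassifier(**hp)
    if spec.family == "random_forest":
        return RandomForestClassifier(**{"n_estimators": 200, "random_state": spec.seed, **hp})
    return MLPClassifier(
        **{
            "hidden_layer_sizes": (32, 16),
            "activation": "relu",
            "solver": "adam",
            "learning_rate_init": spec.learning_rate,
            "max_iter": spec.epochs,
            "random_state": spec.seed,
            **hp,
        }
    )


@dataclass
class FittedModel:
    """A trained estimator bound to the feature space it was trained on."""

    estimator: BaseEstimator
    feature_ids: list[str]
    classes: np.ndarray
    spec: ModelSpec
    best_params: dict

    def predict(self, matrix) -> np.ndarray:
        if list(matrix.feature_ids) != self.feature_ids:
            raise ValidationError("feature mismatch between model and data")
        return self.estimator.predict(matrix.values)


@dataclass
class PredictionResult:
    """Aligned predictions and truth for one evaluation split."""

    sample_ids: list[str]
    predicted: np.ndarray
    true: np.ndarray
    accuracy: float

    def __post_init__(self) -> None:
        if not (len(self.sample_ids) == len(self.predicted) == len(self.true)):
            raise ValidationError("prediction result fields must have equal length")

    @property
    def errors(self) -> np.ndarray:
        """Binary misclassification indicators (1 = wrong)."""
        return (np.asarray(self.predicted) != np.asarray(self.true)).astype(int)


def _cv_splitter(spec: ModelSpec, n_per_class: int):
    folds = min(spec.cv_folds, n_per_class)
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)


def train_model(dataset: CohortDataset, spec: ModelSpec, split: str = "train") -> FittedModel:
    """Fit one family on a cohort split, grid-searching by CV accuracy."""
    ids = dataset.samples_in(split)
    if not ids:
        raise ValidationError(f"no samples tagged {split!r} to train on")
    sub = dataset.subset(ids)
    X = sub.matrix.values
    if np.isnan(X).any():
        raise ValidationError("training matrix contains missing values; impute first")
    y = sub.clinical.labels.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError(f"training target has a single class: {classes[0]!r}")
    grid = spec.grid if spec.grid is not None else DEFAULT_GRIDS[spec.family]
    base = build_estimator(spec)
    n_candidates = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    if n_candidates > 1:
        search = GridSearchCV(
            base, grid, scoring="accuracy", cv=_cv_splitter(spec, counts.min()), refit=True
        )
        search.fit(X, y)
        estimator, best = search.best_estimator_, dict(search.best_params_)
    else:
        params = {k: v[0] for k, v in grid.items()}
        estimator = clone(base).set_params(**params)
        estimator.fit(X, y)
        best = params
    return FittedModel(estimator, sub.matrix.feature_ids, classes, spec, best)


def evaluate(model: FittedModel, dataset: CohortDataset, split: str = "test") -> PredictionResult:
    """Accuracy of a fitted model on one split of a cohort."""
    ids = dataset.sample_ids if split == "all" else dataset.samples_in(split)
    if not ids:
        raise ValidationError(f"no samples tagged {split!r} to evaluate on")
    sub = dataset.subset(ids)
    predicted = model.predict(sub.matrix)
    true = sub.clinical.labels.to_numpy()
    accuracy = float(np.mean(predicted == true))
    return PredictionResult(ids, predicted, true, accuracy)


def out_of_fold_predictions(
    dataset: CohortDataset, spec: ModelSpec, model: FittedModel | None = None,
    n_folds: int = 10, seed: int | None = None,
) -> PredictionResult:
    """Cross-validated predictions for every sample of the cohort.

    The batch analog of prequential evaluation: each sample is predicted by
    a model that never saw it, using the hyperparameters selected during
    training (``model.best_params`` when a fitted model is supplied).
    """
    from sklearn.model_selection import cross_val_predict

    X = dataset.matrix.values
    y = dataset.clinical.labels.to_numpy()
    base = build_estimator(spec)
    if model is not None:
        base = clone(base).set_params(**model.best_params)
    counts = np.unique(y, return_counts=True)[1]
    folds = min(n_folds, counts.min())
    cv = StratifiedKFold(n_splits=folds, shuffle=True,
                         random_state=spec.seed if seed is None else seed)
    predicted = cross_val_predict(base, X, y, cv=cv)
    return PredictionResult(dataset.sample_ids, predicted, y, float(np.mean(predicted == y)))
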