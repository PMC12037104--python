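"""Metabolomics normalization: the eight classical per-feature scalings.

Implements the scaling family standard in metabolomics data pretreatment —
centering, autoscaling (unit variance), pareto, range, vast, level, log10 and
power (square-root) transformation — with parameters estimated on a
designated fitting matrix (normally the training split) and applied unchanged
to held-out data, so evaluation stays leakage-free.

For a feature *i* with training mean :math:`\\bar{x}_i`, sample standard
deviation :math:`s_i` (n-1 denominator), minimum :math:`x_i^{min}` and
maximum :math:`x_i^{max}`:

====================  =====================================================
centering             :math:`x - \\bar{x}_i`
autoscaling           :math:`(x - \\bar{x}_i) / s_i`
pareto                :math:`(x - \\bar{x}_i) / \\sqrt{s_i}`
range                 :math:`(x - \\bar{x}_i) / (x_i^{max} - x_i^{min})`
vast                  :math:`\\frac{x - \\bar{x}_i}{s_i}\\cdot\\frac{\\bar{x}_i}{s_i}`
level                 :math:`(x - \\bar{x}_i) / \\bar{x}_i`
log10                 :math:`\\log_{10} x`
power                 :math:`x^{q}` (default :math:`q = 1/2`)
====================  =====================================================

Features with a zero denominator (constant feature for the sd- and
range-based methods, zero mean for level/vast) fall back to plain centering
with a logged warning rather than producing NaN columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from metadrift.data import MetaboliteMatrix, ValidationError

SCALING_METHODS = (
    "none",
    "centering",
    "autoscaling",
    "pareto",
    "range",
    "vast",
    "level",
    "log10",
    "power",
)

#: methods that are affine in x and therefore exactly invertible from params
AFFINE_METHODS = ("none", "centering", "autoscaling", "pareto", "range", "vast", "level")


@dataclass
class ScalingSpec:
    """Choice of scaling method plus numeric guards."""

    method: str = "autoscaling"
    epsilon: float = 1e-12
    power_exponent: float = 0.5
    log_offset: bool = False  # opt-in epsilon offset for nonpositive log input

    def __post_init__(self) -> None:
        if self.method not in SCALING_METHODS:
            raise ValidationError(
                f"unknown scaling method {self.method!r}; choose from {SCALING_METHODS}"
            )
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")


@dataclass
class ScalingParams:
    """Per-feature statistics estimated on the fitting matrix."""

    feature_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.feature_ids)
        for name in ("mean", "sd", "min", "max"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have one entry per feature")
        if (self.sd < 0).any() or (self.min > self.max).any():
            raise ValidationError("invalid scaling parameters (sd < 0 or min > max)")


class AbundanceScaler(BaseEstimator, TransformerMixin):
    """Per-feature metabolomics scaler with train-fitted parameters.

    A scikit-learn transformer: ``fit`` estimates per-feature mean, sd
    (ddof=1), min and max on the fitting matrix; ``transform`` applies the
    selected method entry-wise. Composes with sklearn pipelines.

    Parameters
    ----------
    method:
        One of ``none, centering, autoscaling, pareto, range, vast, level,
        log10, power``.
    power_exponent:
        Exponent for the power transformation (default 0.5, i.e. square root).
    log_offset:
        If true, log10 shifts nonpositive inputs by ``epsilon - min`` instead
        of raising. Off by default and logged when used.
    """

    def __init__(
        self,
        method: str = "autoscaling",
        epsilon: float = 1e-12,
        power_exponent: float = 0.5,
        log_offset: bool = False,
    ):
        self.method = method
        self.epsilon = epsilon
        self.power_exponent = power_exponent
        self.log_offset = log_offset

    def _spec(self) -> ScalingSpec:
        return ScalingSpec(self.method, self.epsilon, self.power_exponent, self.log_offset)

    def fit(self, X, y=None):
        spec = self._spec()  # validates method
        X = self._as_frame(X)
        if X.isna().to_numpy().any():
            raise ValidationError("scaler requires a complete matrix; impute first")
        self._check_domain(X.to_numpy(), spec)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0).to_numpy()
        self.sd_ = X.std(axis=0, ddof=1).to_numpy()
        if len(X) == 1:
            self.sd_ = np.zeros(X.shape[1])
        self.min_ = X.min(axis=0).to_numpy()
        self.max_ = X.max(axis=0).to_numpy()
        self.log_offset_ = np.where(
            self.min_ <= 0, self.epsilon - np.minimum(self.min_, 0.0), 0.0
        )
        return self

    @property
    def params_(self) -> ScalingParams:
        check_is_fitted(self, "mean_")
        return ScalingParams(
            list(self.feature_names_in_), self.mean_, self.sd_, self.min_, self.max_
        )

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, MetaboliteMatrix):
            return X.data
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))

    def _check_domain(self, values: np.ndarray, spec: ScalingSpec) -> None:
        if spec.method == "log10" and not spec.log_offset and (values <= 0).any():
            raise ValidationError(
                "log10 scaling requires strictly positive values "
                "(enable log_offset to shift nonpositive features)"
            )
        if spec.method == "power" and spec.power_exponent < 1 and (values < 0).any():
            raise ValidationError("power (root) scaling requires non-negative values")

    def _check_features(self, X: pd.DataFrame) -> None:
        if list(map(str, X.columns)) != list(map(str, self.feature_names_in_)):
            raise ValidationError(
                "feature mismatch between fitted scaler and input matrix"
            )

    def transform(self, X):
        check_is_fitted(self, "mean_")
        spec = self._spec()
        frame = self._as_frame(X)
        self._check_features(frame)
        values = frame.to_numpy(dtype=float)
        self._check_domain(values, spec)
        out = _apply_method(values, spec, self.mean_, self.sd_, self.min_, self.max_,
                            self.log_offset_)
        result = pd.DataFrame(out, index=frame.index, columns=frame.columns)
        if isinstance(X, MetaboliteMatrix):
            return MetaboliteMatrix(result)
        if isinstance(X, pd.DataFrame):
            return result
        return out

    def inverse_transform(self, X):
        """Undo the transform (exact for all methods on valid domains)."""
        check_is_fitted(self, "mean_")
        spec = self._spec()
        frame = self._as_frame(X)
        values = frame.to_numpy(dtype=float)
        out = _invert_method(values, spec, self.mean_, self.sd_, self.min_, self.max_,
                             self.log_offset_)
        result = pd.DataFrame(out, index=frame.index, columns=frame.columns)
        if isinstance(X, MetaboliteMatrix):
            return MetaboliteMatrix(result)
        if isinstance(X, pd.DataFrame):
            return result
        return out


def _degenerate_columns(method: str, mean, sd, mn, mx) -> np.ndarray:
    if method in ("autoscaling", "pareto"):
        return sd == 0
    if method == "range":
        return (mx - mn) == 0
    if method == "vast":
        return sd == 0  # mean/sd weight undefined too; sd drives both
    if method == "level":
        return mean == 0
    return np.zeros(len(mean), dtype=bool)


def _apply_method(values, spec, mean, sd, mn, mx, log_offset):
    method = spec.method
    if method == "none":
        return values.copy()
    if method == "log10":
        shifted = values + log_offset if spec.log_offset else values
        if spec.log_offset and log_offset.any():
            warnings.warn("log10: epsilon offset applied to nonpositive features")
        return np.log10(shifted)
    if method == "power":
        return np.power(values, spec.power_exponent)

    centered = values - mean
    degenerate = _degenerate_columns(method, mean, sd, mn, mx)
    if degenerate.any():
        warnings.warn(
            f"{method}: zero denominator for features "
            f"{np.flatnonzero(degenerate).tolist()}; passing centered values through"
        )
    if method == "centering":
        return centered
    if method == "autoscaling":
        denom = np.where(sd == 0, 1.0, sd)
        return centered / denom
    if method == "pareto":
        denom = np.where(sd == 0, 1.0, np.sqrt(sd))
        return centered / denom
    if method == "range":
        span = mx - mn
        denom = np.where(span == 0, 1.0, span)
        return centered / denom
    if method == "vast":
        denom = np.where(sd == 0, 1.0, sd)
        weight = np.where(sd == 0, 1.0, mean / denom)
        return centered / denom * weight
    if method == "level":
        denom = np.where(mean == 0, 1.0, mean)
        return centered / denom
    raise AssertionError(f"unhandled method {method}")


def _invert_method(values, spec, mean, sd, mn, mx, log_offset):
    method = spec.method
    if method == "none":
        return values.copy()
    if method == "log10":
        out = np.power(10.0, values)
        return out - log_offset if spec.log_offset else out
    if method == "power":
        return np.power(values, 1.0 / spec.power_exponent)

    degenerate = _degenerate_columns(method, mean, sd, mn, mx)
    if method == "centering":
        scale = np.ones_like(mean)
    elif method == "autoscaling":
        scale = np.where(sd == 0, 1.0, sd)
    elif method == "pareto":
        scale = np.where(sd == 0, 1.0, np.sqrt(sd))
    elif method == "range":
        span = mx - mn
        scale = np.where(span == 0, 1.0, span)
    elif method == "vast":
        scale = np.where(sd == 0, 1.0, sd * sd / np.where(mean == 0, 1.0, mean))
        scale = np.where(degenerate, 1.0, scale)
    elif method == "level":
        scale = np.where(mean == 0, 1.0, mean)
    else:
        raise AssertionError(f"unhandled method {method}")
    return values * scale + mean


def fit_scaler(matrix: MetaboliteMatrix, spec: ScalingSpec) -> ScalingParams:
    """Estimate per-feature scaling statistics on ``matrix``."""
    scaler = AbundanceScaler(spec.method, spec.epsilon, spec.power_exponent, spec.log_offset)
    return scaler.fit(matrix).params_


def apply_scaler(
    matrix: MetaboliteMatrix, params: ScalingParams, spec: ScalingSpec
) -> MetaboliteMatrix:
    """Apply a scaling with externally supplied (train-fitted) parameters."""
    if params.feature_ids != matrix.feature_ids:
        raise ValidationError("feature mismatch between scaling parameters and matrix")
    scaler = AbundanceScaler(spec.method, spec.epsilon, spec.power_exponent, spec.log_offset)
    scaler.feature_names_in_ = np.asarray(params.feature_ids, dtype=object)
    scaler.n_features_in_ = len(params.feature_ids)
    scaler.mean_ = params.mean
    scaler.sd_ = params.sd
    scaler.min_ = params.min
    scaler.max_ = params.max
    scaler.log_offset_ = np.where(
        params.min <= 0, spec.epsilon - np.minimum(params.min, 0.0), 0.0
    )
    return scaler.transform(matrix)


def scale_train_test(
    dataset, spec: ScalingSpec, fit_on: str = "train"
) -> "MetaboliteMatrix":
    """Scale a cohort's full matrix with parameters fitted on one split.

    ``fit_on`` is normally ``"train"``; ``"all"`` reproduces exploratory
    fit-on-everything figures and is not leakage-free.
    """
    if fit_on == "all":
        fit_ids = dataset.sample_ids
    else:
        fit_ids = dataset.samples_in(fit_on)
        if not fit_ids:
            raise ValidationError(f"no samples in split {fit_on!r} to fit the scaler on")
    params = fit_scaler(dataset.matrix.select_samples(fit_ids), spec)
    return apply_scaler(dataset.matrix, params, spec)
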