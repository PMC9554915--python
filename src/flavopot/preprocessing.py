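"""Train-set-aware preprocessing transformers.

Fixed order inside every model pipeline:

1. missing-pH imputation with the training-set mean;
2. removal of zero-variance features and of features with |Pearson r| >
   0.99 against an earlier retained feature;
3. for the standardized branch (LR/SVR/KNR/GPR): zero-mean unit-variance
   scaling followed by elastic-net feature selection (features with
   non-zero coefficients survive); tree ensembles (RF/XGB) skip step 3.

All transformers are sklearn estimators: every statistic is fitted on
training rows only and replayed on any split, so they compose with
:class:`~sklearn.pipeline.Pipeline` and ``GridSearchCV`` without leakage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import ElasticNet
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


class TrainMeanImputer(BaseEstimator, TransformerMixin):
    """Replace missing values with the training-set column mean.

    By default only the ``pH`` column is imputed (the one descriptor that
    can be missing); pass ``columns=None`` to impute every column with NaNs.
    """

    def __init__(self, columns: tuple[str, ...] | None = ("pH",)):
        self.columns = columns

    def fit(self, X, y=None):
        frame = _as_frame(X)
        cols = [c for c in (self.columns or frame.columns) if c in frame.columns]
        self.fill_values_ = {}
        for col in cols:
            values = frame[col]
            if values.isna().any():
                if values.notna().sum() == 0:
                    raise ValueError(f"column {col!r}: all values missing")
            if values.notna().any():
                self.fill_values_[col] = float(values.mean())
        return self

    def transform(self, X):
        check_is_fitted(self, "fill_values_")
        frame = _as_frame(X).copy()
        for col, value in self.fill_values_.items():
            if col in frame.columns:
                frame[col] = frame[col].fillna(value)
        return frame


class VarianceCorrelationFilter(BaseEstimator, TransformerMixin):
    """Drop zero-variance features, then near-duplicates by Pearson correlation.

    Scanning feature pairs in column order, the *later* column of any pair
    with |r| > ``threshold`` against a retained column is dropped.  Reasons
    are recorded in ``dropped_`` (``zero-variance`` or
    ``correlated-with:<name>``).
    """

    def __init__(self, threshold: float = 0.99):
        self.threshold = threshold

    def fit(self, X, y=None):
        frame = _as_frame(X)
        if len(frame) < 2:
            raise ValueError("need at least 2 training rows")
        self.dropped_: dict[str, str] = {}
        variances = frame.var(axis=0, ddof=0)
        survivors = []
        for col in frame.columns:
            if variances[col] == 0.0:
                self.dropped_[col] = "zero-variance"
            else:
                survivors.append(col)
        values = frame[survivors].to_numpy(dtype=float)
        if survivors:
            corr = np.corrcoef(values, rowvar=False)
            corr = np.atleast_2d(corr)
            keep_mask = np.ones(len(survivors), dtype=bool)
            for i in range(len(survivors)):
                if not keep_mask[i]:
                    continue
                for j in range(i + 1, len(survivors)):
                    if keep_mask[j] and abs(corr[i, j]) > self.threshold:
                        keep_mask[j] = False
                        self.dropped_[survivors[j]] = f"correlated-with:{survivors[i]}"
            survivors = [c for c, keep in zip(survivors, keep_mask) if keep]
        self.selected_features_ = survivors
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        return _as_frame(X)[self.selected_features_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "selected_features_")
        return np.asarray(self.selected_features_, dtype=object)


class FeatureStandardizer(BaseEstimator, TransformerMixin):
    """Zero-mean unit-variance scaling with training statistics, name-preserving."""

    def fit(self, X, y=None):
        frame = _as_frame(X)
        self.scaler_ = StandardScaler().fit(frame.to_numpy(dtype=float))
        self.columns_ = list(frame.columns)
        return self

    def transform(self, X):
        check_is_fitted(self, "scaler_")
        frame = _as_frame(X)
        values = self.scaler_.transform(frame[self.columns_].to_numpy(dtype=float))
        return pd.DataFrame(values, columns=self.columns_, index=frame.index)


class ElasticNetSelector(BaseEstimator, TransformerMixin):
    """Elastic-net feature selection on standardized features.

    Fits the elastic-net cost ``(1/2n)·Σ(y − Xw)² + α·ρ·‖w‖₁ +
    (α(1−ρ)/2)·‖w‖₂²`` by coordinate descent and keeps the features with
    non-zero coefficients.  α weighs both penalties, ρ mixes L1 against L2
    (ρ = 1 is the lasso).  The study grid is α ∈ {10, 100}, ρ ∈
    {0.5, 0.75, 1}, searched jointly with the downstream estimator.

    An empty selection falls back to all input features with a warning.
    """

    def __init__(self, alpha: float = 10.0, rho: float = 1.0,
                 tol: float = 1e-6, max_iter: int = 50_000):
        self.alpha = alpha
        self.rho = rho
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        frame = _as_frame(X)
        if self.alpha == 0.0:
            # unpenalised limit: plain least squares keeps everything
            self.coef_ = np.full(frame.shape[1], np.nan)
            self.selected_features_ = list(frame.columns)
            return self
        model = ElasticNet(
            alpha=self.alpha, l1_ratio=self.rho,
            tol=self.tol, max_iter=self.max_iter,
        )
        model.fit(frame.to_numpy(dtype=float), np.asarray(y, dtype=float))
        self.coef_ = model.coef_.copy()
        mask = self.coef_ != 0.0
        if not mask.any():
            logger.warning(
                "elastic net (alpha=%g, rho=%g) selected no features; "
                "falling back to all %d", self.alpha, self.rho, frame.shape[1],
            )
            mask[:] = True
        self.selected_features_ = [c for c, m in zip(frame.columns, mask) if m]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        return _as_frame(X)[self.selected_features_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "selected_features_")
        return np.asarray(self.selected_features_, dtype=object)


# ---------------------------------------------------------------------------
# Functional wrappers mirroring the transformer surfaces.

def fit_imputer(train_pH: list[float | None]) -> float:
    """Arithmetic mean of the non-missing training pH values."""
    values = np.array([np.nan if v is None else v for v in train_pH], dtype=float)
    if np.all(np.isnan(values)):
        raise ValueError("all training pH values missing")
    return float(np.nanmean(values))


def fit_feature_filter(X_train: pd.DataFrame, threshold: float = 0.99) -> dict[str, str]:
    """Dropped-feature names with reasons (zero-variance / correlated-with)."""
    return VarianceCorrelationFilter(threshold).fit(X_train).dropped_


def fit_standardizer(X_train: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (mean, scale) learned on training rows."""
    std = FeatureStandardizer().fit(X_train)
    return std.scaler_.mean_.copy(), std.scaler_.scale_.copy()


def elastic_net_select(
    X_train_std: pd.DataFrame, y_train, alpha: float = 10.0, rho: float = 1.0
) -> list[str]:
    """Names of features with non-zero elastic-net coefficients."""
    return ElasticNetSelector(alpha=alpha, rho=rho).fit(X_train_std, y_train).selected_features_


def preprocessing_report(pipeline) -> str:
    """Plain-text audit of fitted preprocessing state inside a pipeline."""
    lines = []
    for name, step in getattr(pipeline, "named_steps", {}).items():
        if isinstance(step, TrainMeanImputer) and hasattr(step, "fill_values_"):
            for col, value in step.fill_values_.items():
                lines.append(f"impute\t{col}\t{value:.6g}")
        if isinstance(step, VarianceCorrelationFilter) and hasattr(step, "dropped_"):
            for col, reason in step.dropped_.items():
                lines.append(f"drop\t{col}\t{reason}")
        if isinstance(step, ElasticNetSelector) and hasattr(step, "selected_features_"):
            lines.append(f"select\t{len(step.selected_features_)} features\t"
                         f"alpha={step.alpha} rho={step.rho}")
    return "\n".join(lines)
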