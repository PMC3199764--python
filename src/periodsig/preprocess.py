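"""Normalization pipeline: KNN imputation then per-row standardization.

The same pipeline is applied to the original matrix and to every randomized
matrix before periodicity scores are computed, so that scores are comparable
between original and null data.  Order is fixed: impute, then standardize.

Standard deviation uses the population convention (divide by m) throughout
the package; only consistency matters for score comparability.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import KNNImputer

from .matrix_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class NormalizationConfig:
    """Knobs of the normalization pipeline.

    knn_k : neighbours used for imputation (classic KNNimpute default 10).
    min_observed_fraction : rows observed in fewer than this fraction of
        columns are flagged with a warning (they are still imputed).
    standardize : whether rows are shifted to mean 0 / scaled to sd 1.
    """

    knn_k: int = 10
    min_observed_fraction: float = 0.5
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.knn_k < 1:
            raise ValueError("knn_k must be a positive integer")
        if not 0.0 < self.min_observed_fraction <= 1.0:
            raise ValueError("min_observed_fraction must be in (0, 1]")


class RowStandardizer(TransformerMixin, BaseEstimator):
    """Shift each row to mean 0 and scale it to standard deviation 1.

    Stateless transformer (rows are independent samples); ``fit`` only
    validates input.  Constant rows map to all-zero rows with a warning.
    Idempotent: applying it twice equals applying it once.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("standardization requires a complete matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("standardization requires a complete matrix")
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)  # population convention
        flat = (sd == 0).ravel()
        if flat.any():
            logger.warning(
                "%d constant row(s) mapped to all-zero rows", int(flat.sum())
            )
        sd = np.where(sd == 0, 1.0, sd)
        out = (X - mu) / sd
        out[flat] = 0.0
        return out

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X).transform(X)


class KNNRowImputer(TransformerMixin, BaseEstimator):
    """Impute missing entries from the k nearest gene rows.

    Distances are Euclidean over mutually observed columns; a missing entry
    is replaced by the mean of the ``knn_k`` nearest rows observed at that
    column (scikit-learn's nan-Euclidean KNN imputer).  A row that shares no
    observed column with any donor falls back to its own row mean, with a
    warning.
    """

    def __init__(self, knn_k: int = 10, min_observed_fraction: float = 0.5):
        self.knn_k = knn_k
        self.min_observed_fraction = min_observed_fraction

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        if self.knn_k >= n:
            raise ValueError(f"knn_k={self.knn_k} must be < number of genes n={n}")
        if np.isnan(X).all(axis=0).any():
            j = int(np.flatnonzero(np.isnan(X).all(axis=0))[0])
            raise ValueError(f"column {j + 1} is missing in every row")
        self.n_features_in_ = m
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        if not mask.any():
            return X.copy()
        observed_frac = 1.0 - mask.mean(axis=1)
        low = observed_frac < self.min_observed_fraction
        if low.any():
            logger.warning(
                "%d row(s) observed in < %.0f%% of columns",
                int(low.sum()),
                100 * self.min_observed_fraction,
            )
        # rows with no observed value at all: KNN distances are undefined;
        # fall back to the global mean and warn (degenerate input)
        empty = mask.all(axis=1)
        out = X.copy()
        if empty.any():
            logger.warning("%d fully missing row(s) imputed with global mean",
                           int(empty.sum()))
            out[empty] = np.nanmean(X)
        imputer = KNNImputer(n_neighbors=self.knn_k, weights="uniform")
        result = imputer.fit_transform(out)
        # sklearn silently drops all-NaN columns only; shape is preserved here
        # because fit() rejected such columns.
        return result

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X).transform(X)


def knn_impute(
    matrix: ExpressionMatrix, config: NormalizationConfig | None = None
) -> ExpressionMatrix:
    """KNN-impute missing entries of an expression matrix.

    Observed entries are unchanged; the result has no missing values.
    Idempotent on complete matrices.
    """
    config = config or NormalizationConfig()
    imputer = KNNRowImputer(config.knn_k, config.min_observed_fraction)
    return matrix.with_values(imputer.fit_transform(matrix.values))


def standardize_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Row-standardize a complete expression matrix (mean 0, population sd 1)."""
    return matrix.with_values(RowStandardizer().fit_transform(matrix.values))


def preprocess(
    matrix: ExpressionMatrix, config: NormalizationConfig | None = None
) -> ExpressionMatrix:
    """Full pipeline: impute, then (optionally) standardize."""
    config = config or NormalizationConfig()
    out = knn_impute(matrix, config) if matrix.has_missing else matrix
    if config.standardize:
        out = standardize_rows(out)
    return out
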