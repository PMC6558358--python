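"""Data-cleaning protocol: imputation, outlier screening, SMOTE, mean cancellation.

The pipeline order is fixed: impute -> outlier removal -> SMOTE -> mean
cancellation. Every statistic (column means, imputation values) is a function
of the *training* rows only; transforming held-out rows never updates fitted
parameters.

* Imputation is criticality-aware: gaps in primary (critical) features are
  filled with the feature's training mean, gaps in secondary features with
  the feature's declared default value.
* Outlier screening concatenates the top-5 label-correlated binary features
  of each instance into a 5-bit code and flags instances whose (code, label)
  pair is rarer than ``min_count`` in the training data — the computable
  analog of inspecting a scatter plot of the concatenated feature against
  the label and discarding points far from the central mass.
* SMOTE oversamples the minority class (PTB) to exact parity with the
  majority class by interpolating each synthetic point between a minority
  instance and one of its k nearest minority neighbors.
* Mean cancellation centers every column by its training mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .data import RiskFactorDataset

__all__ = [
    "PreprocParams",
    "Preprocessor",
    "impute_missing",
    "flag_outliers",
    "mean_cancel",
    "smote_balance",
    "default_outlier_min_count",
]


def default_outlier_min_count(n: int) -> int:
    """Default rarity threshold for the (code, label) outlier screen."""
    return max(2, math.ceil(0.001 * n))


@dataclass
class PreprocParams:
    """Fitted preprocessing statistics (training-data functions only).

    Attributes
    ----------
    column_means : ndarray
        Per-column mean of the imputed training matrix; used for mean
        cancellation.
    imputation_values : ndarray
        Per-column fill value for missing cells: the training mean of
        non-missing values for primary features, the schema default for
        secondary features.
    outlier_min_count : int
        Rarity threshold of the (code, label) outlier screen.
    smote_k : int
        Neighbor count for SMOTE interpolation.
    seed : int
        Seed for SMOTE's random draws.
    """

    column_means: np.ndarray | None = None
    imputation_values: np.ndarray | None = None
    outlier_min_count: int = 2
    smote_k: int = 5
    seed: int = 0

    def require_fitted(self) -> None:
        if self.column_means is None or self.imputation_values is None:
            raise RuntimeError("PreprocParams not fitted; call Preprocessor.fit first")


def impute_missing(data: RiskFactorDataset, params: PreprocParams) -> RiskFactorDataset:
    """Fill missing cells using fitted per-feature imputation values."""
    params.require_fitted()
    X = data.X.copy()
    if X.shape[1] != len(params.imputation_values):
        raise ValueError("column count does not match fitted imputation values")
    mask = np.isnan(X)
    if mask.any():
        fill = np.broadcast_to(params.imputation_values, X.shape)
        X[mask] = fill[mask]
    return RiskFactorDataset(X=X, y=data.y.copy(), meta=list(data.meta))


def _codes(X: np.ndarray, top5: Sequence[int]) -> np.ndarray:
    """Concatenate the selected binary columns of each row into an integer code."""
    sub = X[:, list(top5)]
    if np.isnan(sub).any():
        raise ValueError("outlier screen requires imputed (complete) data")
    if (sub < 0).any() or (sub > 1).any():
        raise ValueError("outlier screen features must be binary (values in [0, 1])")
    # mean-imputed cells of binary columns carry fractional values; the
    # code bit is the nearer binary state
    bits = (sub >= 0.5).astype(int)
    weights = 1 << np.arange(bits.shape[1])[::-1]
    return bits @ weights


def flag_outliers(
    data: RiskFactorDataset, top5: Sequence[int], min_count: int
) -> list[int]:
    """Indices of instances whose (5-bit code, label) pair is rare.

    An instance is flagged when the number of instances sharing both its
    concatenated code over the ``top5`` binary features and its label is
    below ``min_count``. Flagged instances are removed by the caller before
    training; the screen is never applied to held-out data.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    codes = _codes(data.X, top5)
    keys = codes * 2 + data.y
    _, inverse, counts = np.unique(keys, return_inverse=True, return_counts=True)
    return np.nonzero(counts[inverse] < min_count)[0].tolist()


def mean_cancel(X: np.ndarray, params: PreprocParams) -> np.ndarray:
    """Center every column by its stored training mean."""
    params.require_fitted()
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(params.column_means):
        raise ValueError(
            f"column count {X.shape[1]} does not match fitted means ({len(params.column_means)})"
        )
    return X - params.column_means


def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    round_binary: bool = False,
    binary_columns: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to parity with SMOTE interpolation.

    Each synthetic sample is ``x + u * (x_nn - x)`` for a random minority
    instance ``x``, one of its ``k`` nearest minority neighbors ``x_nn``
    (Euclidean distance), and ``u ~ Uniform(0, 1)``. Original rows are
    preserved unchanged and come first in the output. With ``round_binary``
    the listed ``binary_columns`` of synthetic rows are rounded back to 0/1.

    Raises
    ------
    ValueError
        If only one class is present or the minority class has < 2 members.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 1:
        raise ValueError("k must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("SMOTE requires both classes present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min < 2:
        raise ValueError("minority class needs >= 2 instances (no neighbor exists)")

    rng = np.random.default_rng(seed)
    Xmin = X[y == minority]
    n_needed = int(n_maj - n_min)
    k_eff = min(k, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xmin)
    neighbors = nn.kneighbors(Xmin, return_distance=False)[:, 1:]  # drop self

    base = rng.integers(0, n_min, size=n_needed)
    pick = rng.integers(0, k_eff, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    x = Xmin[base]
    x_nn = Xmin[neighbors[base, pick]]
    synth = x + u[:, None] * (x_nn - x)
    if round_binary and binary_columns is not None:
        cols = list(binary_columns)
        synth[:, cols] = np.rint(synth[:, cols])

    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=int)])
    return X_out, y_out


class Preprocessor:
    """Fitted preprocessing pipeline: impute -> outlier screen -> SMOTE -> center.

    Parameters
    ----------
    outlier_min_count : int or None
        Rarity threshold for the (code, label) screen; ``None`` uses
        ``max(2, ceil(0.001 n))`` at fit time.
    smote_k, smote_seed : int
        SMOTE neighbor count and seed.
    smote_scope : {"train", "full", "off"}
        "train" applies SMOTE inside :meth:`fit_transform_train` only (the
        default; synthetic samples never reach evaluation data); "full" is
        available for whole-dataset balancing before an external split;
        "off" disables balancing.
    smote_round_binary : bool
        Round synthetic values of binary features back to 0/1.
    top5 : sequence of int or None
        Feature indices for the outlier screen; ``None`` skips the screen
        (used when fewer than 5 binary features are active).
    """

    def __init__(
        self,
        outlier_min_count: int | None = None,
        smote_k: int = 5,
        smote_seed: int = 0,
        smote_scope: str = "train",
        smote_round_binary: bool = False,
        top5: Sequence[int] | None = None,
    ) -> None:
        if smote_scope not in ("train", "full", "off"):
            raise ValueError("smote_scope must be train|full|off")
        self.outlier_min_count = outlier_min_count
        self.smote_k = smote_k
        self.smote_seed = smote_seed
        self.smote_scope = smote_scope
        self.smote_round_binary = smote_round_binary
        self.top5 = list(top5) if top5 is not None else None
        self.params: PreprocParams | None = None

    # -- fitting -----------------------------------------------------------

    def fit(self, train: RiskFactorDataset) -> PreprocParams:
        """Fit imputation values and column means on training rows only."""
        X = train.X
        imputation = np.empty(train.n_features)
        for j, m in enumerate(train.meta):
            col = X[:, j]
            observed = col[~np.isnan(col)]
            if m.is_critical:
                if observed.size == 0:
                    raise ValueError(
                        f"critical feature {m.name!r} has no observed training values; "
                        "mean imputation undefined"
                    )
                imputation[j] = observed.mean()
            else:
                imputation[j] = m.default_value
        filled = X.copy()
        mask = np.isnan(filled)
        filled[mask] = np.broadcast_to(imputation, X.shape)[mask]

        min_count = (
            self.outlier_min_count
            if self.outlier_min_count is not None
            else default_outlier_min_count(train.n)
        )
        self.params = PreprocParams(
            column_means=filled.mean(axis=0),
            imputation_values=imputation,
            outlier_min_count=min_count,
            smote_k=self.smote_k,
            seed=self.smote_seed,
        )
        return self.params

    def fit_transform_train(
        self, train: RiskFactorDataset
    ) -> tuple[np.ndarray, np.ndarray]:
        """Run the full training pipeline; returns the model-ready (X, y).

        Column means for mean cancellation are refit on the post-screen,
        pre-SMOTE training rows so that centering reflects the data the
        model actually trains on.
        """
        self.fit(train)
        clean = impute_missing(train, self.params)

        if self.top5 is not None and len(self.top5) > 0:
            flagged = flag_outliers(clean, self.top5, self.params.outlier_min_count)
            if flagged:
                keep = np.setdiff1d(np.arange(clean.n), flagged)
                clean = clean.subset_rows(keep)

        X, y = clean.X, clean.y
        if self.smote_scope in ("train", "full") and len(np.unique(y)) == 2:
            n_min = np.bincount(y).min()
            if n_min >= 2:
                binary_cols = [j for j, m in enumerate(clean.meta) if m.dtype == "binary"]
                X, y = smote_balance(
                    X,
                    y,
                    k=self.params.smote_k,
                    seed=self.params.seed,
                    round_binary=self.smote_round_binary,
                    binary_columns=binary_cols,
                )
            else:
                warnings.warn("minority class too small for SMOTE; skipping balancing")

        self.params.column_means = X.mean(axis=0)
        return mean_cancel(X, self.params), y

    def transform(self, data: RiskFactorDataset) -> np.ndarray:
        """Apply imputation + mean cancellation to held-out rows.

        No outlier removal and no SMOTE: evaluation data is never resampled
        or filtered, and fitted parameters are never updated.
        """
        if self.params is None:
            raise RuntimeError("Preprocessor not fitted")
        clean = impute_missing(data, self.params)
        return mean_cancel(clean.X, self.params)
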