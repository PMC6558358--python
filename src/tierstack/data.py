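"""Core data types and CSV/schema input-output.

Conventions shared by every module:

* The positive class is preterm birth: ``PTB = 1``. Term birth maps to 0.
  Metrics, SMOTE minority detection and vote tie-breaks all rely on this.
* Risk factors carry a *criticality* flag: ``primary`` factors are the
  critical clinical indicators, ``secondary`` factors the behavioral/social
  ones. The flag drives imputation (mean for primary, declared default for
  secondary) and the experiment feature subsets.
* Missing cells are represented as ``NaN`` in the feature matrix; they are
  flagged on read, never silently zeroed or dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FeatureMeta",
    "RiskFactorDataset",
    "SchemaError",
    "DatasetParseError",
    "load_schema",
    "save_schema",
    "read_dataset",
    "write_dataset",
    "write_predictions",
    "read_predictions",
]

#: Accepted spellings of the outcome labels in a CSV.
_LABEL_MAP = {"PTB": 1, "TB": 0, "1": 1, "0": 0, 1: 1, 0: 0}

PRIMARY = "primary"
SECONDARY = "secondary"


class SchemaError(ValueError):
    """Dataset columns do not match the declared feature schema."""


class DatasetParseError(ValueError):
    """A cell value cannot be interpreted under the schema."""


@dataclass(frozen=True)
class FeatureMeta:
    """Per-feature metadata.

    Parameters
    ----------
    name : str
        Column name, unique within a dataset.
    criticality : {"primary", "secondary"}
        Clinical criticality tier of the risk factor.
    dtype : {"binary", "numeric"}
        Storage/semantic type of the column.
    default_value : float
        Imputation default used for non-critical (secondary) features.
        Must be 0 or 1 for binary features.
    """

    name: str
    criticality: str = SECONDARY
    dtype: str = "binary"
    default_value: float = 0.0

    def __post_init__(self) -> None:
        if self.criticality not in (PRIMARY, SECONDARY):
            raise ValueError(f"criticality must be primary|secondary, got {self.criticality!r}")
        if self.dtype not in ("binary", "numeric"):
            raise ValueError(f"dtype must be binary|numeric, got {self.dtype!r}")
        if self.dtype == "binary" and self.default_value not in (0, 1, 0.0, 1.0):
            raise ValueError(
                f"binary feature {self.name!r}: default_value must be 0 or 1, "
                f"got {self.default_value!r}"
            )

    @property
    def is_critical(self) -> bool:
        return self.criticality == PRIMARY


@dataclass
class RiskFactorDataset:
    """A tabular risk-factor dataset: feature matrix, labels and metadata.

    ``X`` is an ``(n, p)`` float matrix; missing cells are ``NaN``.
    ``y`` is an ``(n,)`` integer vector with 1 = PTB, 0 = TB.
    ``meta`` lists one :class:`FeatureMeta` per column of ``X``.
    """

    X: np.ndarray
    y: np.ndarray
    meta: list[FeatureMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be 0 (TB) or 1 (PTB)")
        if self.meta and len(self.meta) != self.X.shape[1]:
            raise ValueError("meta length must equal the number of feature columns")
        names = [m.name for m in self.meta]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.meta]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.X).any())

    def primary_indices(self) -> list[int]:
        return [j for j, m in enumerate(self.meta) if m.criticality == PRIMARY]

    def secondary_indices(self) -> list[int]:
        return [j for j, m in enumerate(self.meta) if m.criticality == SECONDARY]

    def subset_features(self, indices: Sequence[int]) -> "RiskFactorDataset":
        """Restrict to the given feature columns (labels unchanged)."""
        idx = list(indices)
        return RiskFactorDataset(
            X=self.X[:, idx].copy(),
            y=self.y.copy(),
            meta=[self.meta[j] for j in idx],
        )

    def subset_rows(self, rows: Sequence[int] | np.ndarray) -> "RiskFactorDataset":
        rows = np.asarray(rows)
        return RiskFactorDataset(X=self.X[rows].copy(), y=self.y[rows].copy(), meta=list(self.meta))

    def to_dataframe(self, outcome: str = "outcome") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[outcome] = np.where(self.y == 1, "PTB", "TB")
        return df


# ---------------------------------------------------------------------------
# Schema files


def load_schema(path: str | Path) -> tuple[list[FeatureMeta], str]:
    """Load a YAML/JSON feature schema.

    The schema file maps feature names to criticality, dtype and imputation
    default, plus the name of the outcome column::

        outcome: outcome
        features:
          - {name: prior_ptb, criticality: primary, dtype: binary, default_value: 0}
          ...

    Returns ``(meta, outcome_column)``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "features" not in raw:
        raise SchemaError(f"{path}: schema must be a mapping with a 'features' list")
    outcome = raw.get("outcome", "outcome")
    meta = [
        FeatureMeta(
            name=f["name"],
            criticality=f.get("criticality", SECONDARY),
            dtype=f.get("dtype", "binary"),
            default_value=float(f.get("default_value", 0)),
        )
        for f in raw["features"]
    ]
    return meta, outcome


def save_schema(path: str | Path, meta: Sequence[FeatureMeta], outcome: str = "outcome") -> None:
    doc = {
        "outcome": outcome,
        "features": [
            {
                "name": m.name,
                "criticality": m.criticality,
                "dtype": m.dtype,
                "default_value": float(m.default_value),
            }
            for m in meta
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Dataset CSV input/output


def read_dataset(
    path: str | Path,
    schema: Sequence[FeatureMeta] | str | Path,
    outcome: str = "outcome",
) -> RiskFactorDataset:
    """Read a patient CSV into a :class:`RiskFactorDataset`.

    ``schema`` is either a list of :class:`FeatureMeta` or the path of a
    schema file (in which case its outcome column name wins). Empty cells and
    ``NA`` are flagged as missing (``NaN``); rows are never dropped. Outcome
    values may be ``PTB``/``TB`` or ``1``/``0``; anything else raises
    :class:`DatasetParseError`.
    """
    if isinstance(schema, (str, Path)):
        meta, outcome = load_schema(schema)
    else:
        meta = list(schema)

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"": np.nan, "NA": np.nan})

    names = [m.name for m in meta]
    missing_cols = [c for c in names + [outcome] if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: columns missing from CSV: {missing_cols}")
    unknown = [c for c in df.columns if c not in names and c != outcome]
    if unknown:
        raise SchemaError(f"{path}: columns not in schema: {unknown}")

    raw_y = df[outcome]
    if raw_y.isna().any():
        raise DatasetParseError(f"{path}: outcome column {outcome!r} has missing values")
    y = np.empty(len(df), dtype=int)
    for i, v in enumerate(raw_y):
        key = v.strip() if isinstance(v, str) else v
        if key not in _LABEL_MAP:
            raise DatasetParseError(
                f"{path}: outcome value {v!r} at row {i} is not one of PTB, TB, 0, 1"
            )
        y[i] = _LABEL_MAP[key]

    try:
        X = df[names].astype(float).to_numpy()
    except ValueError as exc:
        raise DatasetParseError(f"{path}: non-numeric feature cell: {exc}") from exc
    return RiskFactorDataset(X=X, y=y, meta=meta)


def write_dataset(path: str | Path, data: RiskFactorDataset, outcome: str = "outcome") -> None:
    """Write a dataset as CSV (missing cells become empty fields).

    Binary columns are written as integers so the file round-trips
    bit-exactly through :func:`read_dataset`.
    """
    df = pd.DataFrame(index=range(data.n))
    for j, m in enumerate(data.meta):
        col = data.X[:, j]
        if m.dtype == "binary":
            s = pd.Series(col).map(lambda v: "" if np.isnan(v) else str(int(v)))
        else:
            s = pd.Series(col).map(lambda v: "" if np.isnan(v) else repr(float(v)))
        df[m.name] = s
    df[outcome] = np.where(data.y == 1, "PTB", "TB")
    df.to_csv(path, index=False)


def write_predictions(
    path: str | Path,
    ids: Sequence,
    scores: Sequence[float],
    labels: Sequence[int],
) -> None:
    """Write per-patient predictions as CSV with columns id, ptb_score, ptb_label."""
    ids = list(ids)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (len(ids) == len(scores) == len(labels)):
        raise ValueError(
            f"length mismatch: ids={len(ids)}, scores={len(scores)}, labels={len(labels)}"
        )
    pd.DataFrame({"id": ids, "ptb_score": scores, "ptb_label": labels}).to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a predictions CSV written by :func:`write_predictions`."""
    df = pd.read_csv(path)
    expected = ["id", "ptb_score", "ptb_label"]
    if list(df.columns) != expected:
        raise DatasetParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df
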