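"""Metrics and the repeated-trial experiment harness.

Metrics follow the usual binary-classification definitions with PTB = 1 as
the positive class: accuracy, precision, sensitivity (PTB recall), F1 and
trapezoidal AUC under the ROC curve. The harness runs each experiment over
``n_trials`` independent stratified 80/20 train/test splits (re-seeded per
trial), preprocesses and fits on the training part only, evaluates on the
held-out part, and reports macro averages (means of per-trial metrics).

Experiments restrict the feature space by criticality-based subset rules
(all factors, primary only, all secondary, top-5 secondary, primary plus
top-5 secondary) and compare the proposed tiered ensemble against the
traditional stacked ensemble on paired splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import train_test_split

from .data import RiskFactorDataset
from .feature_select import rank_by_correlation, select_top_k
from .preprocessing import Preprocessor
from .stacking import (
    CombinationScheme,
    LearnerSpec,
    TieredStacking,
    TraditionalStacking,
    default_learners,
    default_schemes,
)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ExperimentSpec",
    "HarnessConfig",
    "compute_metrics",
    "roc_curve",
    "resolve_feature_subset",
    "preprocess_training_data",
    "run_experiment",
    "compare_algorithms",
    "ComparisonResult",
    "default_experiment_specs",
    "plot_roc_grid",
]

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "f1", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with PTB = 1 as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred lengths differ")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class MetricsReport:
    """Evaluation metrics, either for one trial or averaged across trials.

    ``per_trial`` retains the individual trial rows so macro averaging is
    auditable; ``roc_curves`` keeps one (fpr, tpr) curve per trial.
    """

    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    auc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    n_trials: int = 1
    per_trial: pd.DataFrame | None = None
    roc_curves: list[list[tuple[float, float]]] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}

    @classmethod
    def from_trials(cls, trials: Sequence["MetricsReport"]) -> "MetricsReport":
        """Macro average: the mean of per-trial metric values."""
        if not trials:
            raise ValueError("no trials to aggregate")
        df = pd.DataFrame(
            [{"trial": t, **r.as_dict()} for t, r in enumerate(trials)]
        )
        means = df[list(METRIC_NAMES)].mean()
        return cls(
            **{m: float(means[m]) for m in METRIC_NAMES},
            roc_points=list(trials[0].roc_points),
            n_trials=len(trials),
            per_trial=df,
            roc_curves=[list(r.roc_points) for r in trials],
        )


def roc_curve(y_true: np.ndarray, y_score: np.ndarray) -> list[tuple[float, float]]:
    """ROC points (fpr, tpr), threshold swept over unique scores descending.

    Starts at (0, 0) and ends at (1, 1); both coordinates are monotone
    non-decreasing. Raises on single-class ``y_true``.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if np.unique(y_true).size < 2:
        raise ValueError("ROC curve undefined for single-class labels")
    fpr, tpr, _ = _sk_roc_curve(y_true, y_score, drop_intermediate=False)
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, y_score: np.ndarray
) -> MetricsReport:
    """Single-trial metrics from hard labels and PTB scores.

    accuracy = (tp+tn)/n, precision = tp/(tp+fp) (0 with a warning when no
    positives are predicted), sensitivity = tp/(tp+fn), F1 the harmonic
    mean of precision and sensitivity, AUC the trapezoidal area under the
    ROC built from ``y_score``.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if not (len(y_true) == len(y_pred) == len(y_score)):
        raise ValueError("y_true, y_pred, y_score lengths differ")
    cc = ConfusionCounts.from_labels(y_true, y_pred)

    accuracy = (cc.tp + cc.tn) / cc.n
    if cc.tp + cc.fp == 0:
        warnings.warn("no positive predictions; precision defined as 0")
        precision = 0.0
    else:
        precision = cc.tp / (cc.tp + cc.fp)
    sensitivity = cc.tp / (cc.tp + cc.fn) if (cc.tp + cc.fn) > 0 else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if (precision + sensitivity) > 0
        else 0.0
    )
    pts = roc_curve(y_true, y_score)
    fpr, tpr = zip(*pts)
    return MetricsReport(
        accuracy=float(accuracy),
        precision=float(precision),
        sensitivity=float(sensitivity),
        f1=float(f1),
        auc=float(_trapezoid_auc(np.array(fpr), np.array(tpr))),
        roc_points=pts,
    )


# ---------------------------------------------------------------------------
# Experiment specification and harness


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment: a feature-subset rule evaluated over repeated trials.

    ``feature_subset`` is one of ``all``, ``primary_only``,
    ``secondary_only``, ``top5_secondary``, ``primary_plus_top5_secondary``
    or an explicit list of feature indices.
    """

    name: str
    feature_subset: str | tuple[int, ...] = "all"
    n_trials: int = 10
    base_seed: int = 0


def default_experiment_specs(n_trials: int = 10, base_seed: int = 0) -> list[ExperimentSpec]:
    """The five default criticality-based experiments."""
    return [
        ExperimentSpec("all_factors", "all", n_trials, base_seed),
        ExperimentSpec("primary_only", "primary_only", n_trials, base_seed),
        ExperimentSpec("all_secondary", "secondary_only", n_trials, base_seed),
        ExperimentSpec("top5_secondary", "top5_secondary", n_trials, base_seed),
        ExperimentSpec(
            "primary_plus_top5_secondary", "primary_plus_top5_secondary", n_trials, base_seed
        ),
    ]


@dataclass
class HarnessConfig:
    """Tunables of the evaluation harness (learner roster, schemes, splits)."""

    learners: list[LearnerSpec] = field(default_factory=default_learners)
    schemes: list[CombinationScheme] = field(default_factory=default_schemes)
    meta_learner: LearnerSpec = field(default_factory=lambda: LearnerSpec("logistic"))
    k_meta: int = 3
    k_outlier: int = 5
    n_folds: int = 10
    test_size: float = 0.2
    smote_k: int = 5
    smote_scope: str = "train"
    smote_round_binary: bool = False
    outlier_min_count: int | None = None


def _rank_with_nan_fill(X: np.ndarray, y: np.ndarray):
    """Correlation ranking tolerant of missing cells (column-mean filled)."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        means = np.nan_to_num(means)
        X = np.where(np.isnan(X), means, X)
    return rank_by_correlation(X, y)


def resolve_feature_subset(
    data: RiskFactorDataset, rule: str | Sequence[int]
) -> list[int]:
    """Map a subset rule to concrete feature indices of ``data``.

    ``top5_secondary`` ranks the secondary features by |correlation| with
    the label over the whole dataset (the analog of a fixed clinical
    shortlist) and keeps the best five.
    """
    if not isinstance(rule, str):
        idx = list(rule)
        if not idx:
            raise ValueError("explicit feature subset is empty")
        return idx
    if rule == "all":
        return list(range(data.n_features))
    if rule == "primary_only":
        idx = data.primary_indices()
    elif rule == "secondary_only":
        idx = data.secondary_indices()
    elif rule in ("top5_secondary", "primary_plus_top5_secondary"):
        sec = data.secondary_indices()
        if not sec:
            raise ValueError("dataset has no secondary features")
        ranking = _rank_with_nan_fill(data.X[:, sec], data.y)
        top = [sec[j] for j in select_top_k(ranking, min(5, len(sec)))]
        idx = sorted(top) if rule == "top5_secondary" else data.primary_indices() + sorted(top)
    else:
        raise ValueError(f"unknown feature-subset rule {rule!r}")
    if not idx:
        raise ValueError(f"subset rule {rule!r} selects no features")
    return idx


def _four_case_strata(data: RiskFactorDataset) -> np.ndarray:
    """Stratum id combining the label with any-primary-factor presence.

    Falls back to label-only strata when a combined stratum is too small
    for a stratified split (or when no primary features exist).
    """
    prim = data.primary_indices()
    if not prim:
        return data.y
    active = np.nan_to_num(data.X[:, prim]).any(axis=1).astype(int)
    strata = active * 2 + data.y
    _, counts = np.unique(strata, return_counts=True)
    if counts.min() < 2 or len(counts) < 4:
        return data.y
    return strata


def preprocess_training_data(
    train: RiskFactorDataset, config: HarnessConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, Preprocessor]:
    """Fit the full cleaning pipeline on a training partition.

    Selects the outlier-screen features by correlation on the training
    rows, then runs impute -> screen -> SMOTE -> mean-cancel. Returns the
    model-ready matrix and labels plus the fitted :class:`Preprocessor`
    (use its ``transform`` for held-out data).
    """
    # outlier screen: top-k_outlier binary features by |correlation| on train
    binary = [j for j, m in enumerate(train.meta) if m.dtype == "binary"]
    top5: list[int] | None = None
    if binary and len(np.unique(train.y)) == 2:
        ranking = _rank_with_nan_fill(train.X[:, binary], train.y)
        k = min(config.k_outlier, len(binary))
        top5 = [binary[j] for j in select_top_k(ranking, k)]
    prep = Preprocessor(
        outlier_min_count=config.outlier_min_count,
        smote_k=config.smote_k,
        smote_seed=seed,
        smote_scope=config.smote_scope,
        smote_round_binary=config.smote_round_binary,
        top5=top5,
    )
    Xtr, ytr = prep.fit_transform_train(train)
    return Xtr, ytr, prep


# internal alias kept for the harness
_preprocess_trial = preprocess_training_data


def _fit_algo(
    algo: str, Xtr: np.ndarray, ytr: np.ndarray, config: HarnessConfig, seed: int
):
    k_meta = min(config.k_meta, Xtr.shape[1])
    if algo == "proposed":
        return TieredStacking(
            Xtr, ytr,
            learners=config.learners, schemes=config.schemes,
            meta_learner=config.meta_learner, k_meta=k_meta,
            n_folds=config.n_folds, seed=seed,
        ).fit()
    if algo == "traditional_se":
        return TraditionalStacking(
            Xtr, ytr,
            learners=config.learners, meta_learner=config.meta_learner,
            n_folds=config.n_folds, seed=seed,
        ).fit()
    raise ValueError(f"unknown algorithm {algo!r}; use proposed|traditional_se")


def run_experiment(
    data: RiskFactorDataset,
    spec: ExperimentSpec,
    algo: str = "proposed",
    config: HarnessConfig | None = None,
) -> MetricsReport:
    """Repeated-trial evaluation of one algorithm on one feature subset.

    Per trial *t*: seed ``base_seed + t``; stratified 80/20 train/test row
    split preserving the four-case (risk-factor x outcome) mix; the
    cleaning pipeline is fitted on the training rows only; the model is fit
    and then evaluated on the untouched test rows. The report averages the
    per-trial metrics (macro averaging).
    """
    config = config or HarnessConfig()
    subset = resolve_feature_subset(data, spec.feature_subset)
    if spec.feature_subset == "all" and len(subset) < 4:
        raise ValueError("'all' experiments require at least 4 features")
    strata = _four_case_strata(data)

    trials = []
    for t in range(spec.n_trials):
        seed = spec.base_seed + t
        idx_train, idx_test = train_test_split(
            np.arange(data.n),
            test_size=config.test_size,
            random_state=seed,
            stratify=strata,
        )
        train = data.subset_rows(idx_train).subset_features(subset)
        test = data.subset_rows(idx_test).subset_features(subset)
        Xtr, ytr, prep = _preprocess_trial(train, config, seed)
        res = _fit_algo(algo, Xtr, ytr, config, seed)
        Xte = prep.transform(test)
        scores, labels = res.predict(Xte)
        trials.append(compute_metrics(test.y, labels, scores))
    return MetricsReport.from_trials(trials)


@dataclass
class ComparisonResult:
    """Proposed-vs-SE comparison across experiments.

    ``table`` has one row per (experiment, algorithm) with mean metrics;
    ``differences`` one row per experiment with proposed − SE deltas;
    ``reports`` maps (experiment, algorithm) to the full MetricsReport.
    """

    table: pd.DataFrame
    differences: pd.DataFrame
    reports: dict[tuple[str, str], MetricsReport]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def per_trial_table(self) -> pd.DataFrame:
        rows = []
        for (spec, algo), rep in self.reports.items():
            if rep.per_trial is not None:
                df = rep.per_trial.copy()
                df.insert(0, "algorithm", algo)
                df.insert(0, "experiment", spec)
                rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def to_text(self) -> str:
        lines = ["Experiment comparison: proposed tiered ensemble vs traditional SE", ""]
        lines.append(self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        lines.append("Per-metric difference (proposed - SE):")
        lines.append(
            self.differences.to_string(index=False, float_format=lambda v: f"{v:+.4f}")
        )
        return "\n".join(lines)


def compare_algorithms(
    data: RiskFactorDataset,
    specs: Sequence[ExperimentSpec] | None = None,
    config: HarnessConfig | None = None,
) -> ComparisonResult:
    """Run every experiment for both algorithms on paired splits."""
    specs = list(specs) if specs is not None else default_experiment_specs()
    if not specs:
        raise ValueError("need at least one experiment spec")
    config = config or HarnessConfig()

    rows, diffs, reports = [], [], {}
    for spec in specs:
        per_algo = {}
        for algo in ("proposed", "traditional_se"):
            rep = run_experiment(data, spec, algo=algo, config=config)
            per_algo[algo] = rep
            reports[(spec.name, algo)] = rep
            rows.append({"experiment": spec.name, "algorithm": algo, **rep.as_dict()})
        diffs.append(
            {
                "experiment": spec.name,
                **{
                    m: per_algo["proposed"].as_dict()[m]
                    - per_algo["traditional_se"].as_dict()[m]
                    for m in METRIC_NAMES
                },
            }
        )
    return ComparisonResult(
        table=pd.DataFrame(rows), differences=pd.DataFrame(diffs), reports=reports
    )


def plot_roc_grid(result: ComparisonResult, path: str | Path) -> None:
    """ROC grid: one column per experiment, SE on the top row, proposed below.

    Per-trial curves in light gray, the first trial highlighted; the
    chance diagonal dotted at the 50% mark.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(dict.fromkeys(spec for spec, _ in result.reports))
    fig, axes = plt.subplots(2, len(names), figsize=(3.2 * len(names), 6.4), squeeze=False)
    for col, name in enumerate(names):
        for row, algo in enumerate(("traditional_se", "proposed")):
            ax = axes[row][col]
            rep = result.reports[(name, algo)]
            for curve in rep.roc_curves or [rep.roc_points]:
                fpr, tpr = zip(*curve)
                ax.plot(fpr, tpr, color="gray", alpha=0.4, lw=0.8)
            fpr, tpr = zip(*rep.roc_points)
            ax.plot(fpr, tpr, color="C0", lw=1.5)
            ax.plot([0, 1], [0, 1], "k:", lw=0.8)
            ax.set_title(f"{name}\n{algo} (AUC={rep.auc:.3f})", fontsize=8)
            ax.set_xlim(0, 1)
            ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
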