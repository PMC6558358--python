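"""The three-tier stacked ensemble and the traditional stacking baseline.

Tier 1 (base tier) trains a roster of diverse classifiers under stratified
k-fold cross-validation, yielding out-of-fold (OOF) probability scores: the
score for instance *i* from learner *j* always comes from the model trained
on the folds that exclude *i*. Tier 2 (ensemble tier) applies fixed
combination schemes — averaging, majority vote, max-score, product rule —
row-wise to the OOF predictions; each scheme contributes one meta-feature.
Tier 3 (generalization tier) trains a meta-learner on the meta-features
concatenated with the top-k (default 3) raw features most correlated with
the label.

The traditional stacked ensemble (SE) baseline trains the meta-learner
directly on the n x m OOF score matrix, with no combination schemes and no
appended raw features. Both variants share the same fold plan under a
common seed, so comparisons are paired.

Modelling API follows the model/results convention: construct a model from
data, call ``fit()``, get a results object that predicts and summarises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .feature_select import rank_by_correlation, select_top_k

__all__ = [
    "FoldPlan",
    "OOFPredictions",
    "LearnerSpec",
    "CombinationScheme",
    "PassThroughClassifier",
    "SigmoidMarginSVC",
    "make_learner",
    "make_scheme",
    "default_learners",
    "default_schemes",
    "make_stratified_folds",
    "fit_base_tier",
    "combine_average",
    "combine_majority",
    "build_meta_features",
    "TieredStacking",
    "TraditionalStacking",
    "TieredStackingResults",
    "fit_tiered_ensemble",
    "fit_traditional_se",
]

SERIAL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Fold planning


@dataclass(frozen=True)
class FoldPlan:
    """Stratified assignment of instances to disjoint folds.

    ``assignments[i]`` is the fold index of instance *i* in
    ``[0, n_folds)``. Per-fold positive-class counts differ from perfect
    proportionality by at most one.
    """

    assignments: np.ndarray
    n_folds: int

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments)
        if a.min() < 0 or a.max() >= self.n_folds:
            raise ValueError("fold indices out of range")
        if len(np.unique(a)) != self.n_folds:
            raise ValueError("every fold must be non-empty")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments != fold)[0]


def make_stratified_folds(y: np.ndarray, n_folds: int = 10, seed: int = 0) -> FoldPlan:
    """Partition instances into stratified, disjoint, exhaustive folds.

    Shuffled instances of each class are dealt round-robin across folds
    (the deal position carries over between classes so fold sizes also
    balance), which guarantees per-fold counts of *every* class differ by
    at most 1 — even when a class is smaller than ``n_folds``.
    Reproducible under a fixed seed.
    """
    y = np.asarray(y, dtype=int)
    if len(y) < n_folds:
        raise ValueError(f"n={len(y)} < n_folds={n_folds}")
    rng = np.random.default_rng(seed)
    assignments = np.empty(len(y), dtype=int)
    pos = 0
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        for i, inst in enumerate(idx):
            assignments[inst] = (pos + i) % n_folds
        pos += len(idx)
    return FoldPlan(assignments=assignments, n_folds=n_folds)


# ---------------------------------------------------------------------------
# Learners


class PassThroughClassifier(BaseEstimator, ClassifierMixin):
    """Identity meta-learner: the PTB score is the first input column.

    Used for degenerate configurations (e.g. reducing the tiered model to a
    plain soft vote) and in equivalence tests.
    """

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p = np.clip(np.asarray(X, dtype=float)[:, 0], 0.0, 1.0)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class SigmoidMarginSVC(BaseEstimator, ClassifierMixin):
    """Linear-kernel SVM scored through a logistic squashing of its margin.

    ``predict_proba`` maps the signed decision-function margin through
    ``1 / (1 + exp(-d))``, giving a monotone [0, 1] score without the
    5-fold internal calibration of ``SVC(probability=True)``.
    """

    def __init__(self, C: float = 1.0, random_state: int | None = None):
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        self.svc_ = SVC(kernel="linear", C=self.C, random_state=self.random_state)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict_proba(self, X):
        d = self.svc_.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-d))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return self.svc_.predict(X)


@dataclass(frozen=True)
class LearnerSpec:
    """A named classifier with hyperparameters, resolvable via the registry."""

    identifier: str
    hyperparameters: dict = field(default_factory=dict)


_LEARNER_REGISTRY: dict[str, Callable[..., BaseEstimator]] = {
    "logistic": lambda **kw: LogisticRegression(max_iter=1000, **kw),
    "decision_tree": lambda **kw: DecisionTreeClassifier(**kw),
    "naive_bayes": lambda **kw: GaussianNB(**kw),
    "knn": lambda **kw: KNeighborsClassifier(**{"n_neighbors": 5, **kw}),
    "svm_linear": lambda **kw: SigmoidMarginSVC(**kw),
    "passthrough": lambda **kw: PassThroughClassifier(**kw),
}

_SEEDED_LEARNERS = {"decision_tree", "svm_linear", "logistic"}


def register_learner(identifier: str, factory: Callable[..., BaseEstimator]) -> None:
    _LEARNER_REGISTRY[identifier] = factory


def make_learner(spec: LearnerSpec, seed: int | None = None) -> BaseEstimator:
    """Instantiate a classifier from its spec; seeds stochastic learners."""
    if spec.identifier not in _LEARNER_REGISTRY:
        raise KeyError(
            f"unknown learner {spec.identifier!r}; known: {sorted(_LEARNER_REGISTRY)}"
        )
    kw = dict(spec.hyperparameters)
    if seed is not None and spec.identifier in _SEEDED_LEARNERS and "random_state" not in kw:
        kw["random_state"] = seed
    return _LEARNER_REGISTRY[spec.identifier](**kw)


def default_learners() -> list[LearnerSpec]:
    """Default base-tier roster: five diverse, moderately performing learners.

    Tree depth/leaf-size limits and the k of the nearest-neighbor learner
    are sized for training sets of a few thousand rows of mostly binary
    clinical indicators; unpruned trees or very small k overfit such data
    and make poor base learners for stacking.
    """
    return [
        LearnerSpec("logistic"),
        LearnerSpec("decision_tree", {"max_depth": 5, "min_samples_leaf": 25}),
        LearnerSpec("naive_bayes"),
        LearnerSpec("knn", {"n_neighbors": 25}),
        LearnerSpec("svm_linear"),
    ]


def _score(est: BaseEstimator, X: np.ndarray) -> np.ndarray:
    """PTB probability in [0, 1] from a fitted classifier."""
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(X)
        pos = int(np.nonzero(est.classes_ == 1)[0][0]) if 1 in est.classes_ else proba.shape[1] - 1
        return np.clip(proba[:, pos], 0.0, 1.0)
    # hard-output learners: score in {0, 1}
    return est.predict(X).astype(float)


# ---------------------------------------------------------------------------
# Base tier


@dataclass
class OOFPredictions:
    """Out-of-fold base-learner predictions.

    ``scores[i, j]`` is learner *j*'s cross-validated probability that
    instance *i* is PTB; ``labels`` thresholds the scores at 0.5. Every
    cell is filled exactly once, from the fold where *i* was held out.
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels shapes differ")
        if np.isnan(self.scores).any():
            raise ValueError("OOF scores contain unfilled cells")
        if (self.scores < 0).any() or (self.scores > 1).any():
            raise ValueError("OOF scores outside [0, 1]")


def fit_base_tier(
    X: np.ndarray,
    y: np.ndarray,
    learners: Sequence[LearnerSpec],
    folds: FoldPlan,
    seed: int = 0,
) -> tuple[OOFPredictions, list[BaseEstimator]]:
    """Cross-validated base tier: OOF scores plus full-data refits.

    For each learner and each fold, the learner is trained on the other
    folds and scores the held-out fold, so every (instance, learner) cell is
    written exactly once. Each learner is additionally refit on all rows for
    deployment-time prediction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(learners) < 1:
        raise ValueError("base tier needs at least one learner")
    n, m = X.shape[0], len(learners)
    scores = np.full((n, m), np.nan)
    fitted: list[BaseEstimator] = []
    for j, spec in enumerate(learners):
        for fold in range(folds.n_folds):
            tr, te = folds.train_indices(fold), folds.test_indices(fold)
            est = make_learner(spec, seed=seed)
            try:
                est.fit(X[tr], y[tr])
            except Exception as exc:
                raise RuntimeError(
                    f"learner {spec.identifier!r} failed to fit on fold {fold}: {exc}"
                ) from exc
            scores[te, j] = _score(est, X[te])
        full = make_learner(spec, seed=seed)
        full.fit(X, y)
        fitted.append(full)
    labels = (scores >= 0.5).astype(int)
    return OOFPredictions(scores=scores, labels=labels), fitted


# ---------------------------------------------------------------------------
# Ensemble tier: combination schemes


def combine_average(scores: Sequence[float]) -> float:
    """Arithmetic mean of per-learner scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot average an empty score vector")
    return float(scores.mean())


def combine_majority(labels: Sequence[int]) -> int:
    """Modal hard label; an exact tie resolves to PTB (1).

    Predicting PTB on a tie is the conservative clinical choice: a false
    negative (missed PTB) withholds treatment from a patient who needs it.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("cannot vote on an empty label vector")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("vote labels must be 0/1")
    ones = int(labels.sum())
    return 1 if ones * 2 >= labels.size else 0


@dataclass(frozen=True)
class CombinationScheme:
    """A fixed rule merging per-learner outputs for one instance.

    ``kind`` selects the input: "score" schemes see the m-vector of
    probability scores, "label" schemes the m-vector of hard labels.
    Output must lie in [0, 1] and be invariant to learner permutation.
    """

    identifier: str
    kind: str  # "score" | "label"
    combine: Callable[[np.ndarray], float]

    def apply_rows(self, M: np.ndarray) -> np.ndarray:
        return np.array([float(self.combine(row)) for row in M])


def _combine_max(scores: np.ndarray) -> float:
    return float(np.max(scores))


def _combine_product(scores: np.ndarray) -> float:
    # geometric mean = m-th root of the product, keeping the output in [0,1]
    return float(np.prod(scores) ** (1.0 / len(scores)))


def _combine_average_rule(scores: np.ndarray) -> float:
    return combine_average(scores)


def _combine_majority_rule(labels: np.ndarray) -> float:
    return float(combine_majority(labels))


_SCHEME_REGISTRY: dict[str, CombinationScheme] = {
    "average": CombinationScheme("average", "score", _combine_average_rule),
    "majority": CombinationScheme("majority", "label", _combine_majority_rule),
    "max_score": CombinationScheme("max_score", "score", _combine_max),
    "product": CombinationScheme("product", "score", _combine_product),
}


def register_scheme(scheme: CombinationScheme) -> None:
    _SCHEME_REGISTRY[scheme.identifier] = scheme


def make_scheme(identifier: str) -> CombinationScheme:
    if identifier not in _SCHEME_REGISTRY:
        raise KeyError(f"unknown scheme {identifier!r}; known: {sorted(_SCHEME_REGISTRY)}")
    return _SCHEME_REGISTRY[identifier]


def default_schemes() -> list[CombinationScheme]:
    """Default ensemble-tier schemes: averaging, majority, max, product rule."""
    return [make_scheme(s) for s in ("average", "majority", "max_score", "product")]


def build_meta_features(
    oof: OOFPredictions, schemes: Sequence[CombinationScheme]
) -> np.ndarray:
    """Apply each scheme row-wise to the OOF predictions -> (n, s) matrix."""
    if len(schemes) < 1:
        raise ValueError("need at least one combination scheme")
    cols = []
    for scheme in schemes:
        M = oof.scores if scheme.kind == "score" else oof.labels
        col = scheme.apply_rows(M)
        if (col < 0).any() or (col > 1).any():
            raise ValueError(f"scheme {scheme.identifier!r} produced output outside [0, 1]")
        cols.append(col)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Models and results


class _StackingBase:
    """Shared machinery for the tiered model and the traditional SE baseline."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        learners: Sequence[LearnerSpec] | None = None,
        meta_learner: LearnerSpec | None = None,
        n_folds: int = 10,
        seed: int = 0,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if np.isnan(self.X).any():
            raise ValueError("input matrix contains missing values; preprocess first")
        self.learners = list(learners) if learners is not None else default_learners()
        self.meta_learner = meta_learner or LearnerSpec("logistic")
        self.n_folds = n_folds
        self.seed = seed

    def _base_tier(self) -> tuple[FoldPlan, OOFPredictions, list[BaseEstimator]]:
        folds = make_stratified_folds(self.y, self.n_folds, self.seed)
        oof, fitted = fit_base_tier(self.X, self.y, self.learners, folds, seed=self.seed)
        return folds, oof, fitted


class TieredStacking(_StackingBase):
    """Three-tier stacked ensemble model.

    Parameters
    ----------
    X, y : arrays
        Preprocessed training matrix (no missing values) and 0/1 labels
        (1 = PTB).
    learners : list of LearnerSpec, optional
        Base-tier roster; defaults to logistic regression, decision tree,
        Gaussian naive Bayes, 5-NN, and a linear SVM.
    schemes : list of CombinationScheme, optional
        Ensemble-tier combination schemes; defaults to averaging, majority
        vote, max-score and the product rule.
    meta_learner : LearnerSpec, optional
        Generalization-tier learner; defaults to logistic regression.
    k_meta : int
        Number of top label-correlated raw features appended to the
        meta-features (default 3).
    n_folds, seed : int
        Cross-validation folds for the base tier and the random seed.

    Examples
    --------
    >>> model = TieredStacking(X, y, seed=7)
    >>> res = model.fit()
    >>> scores, labels = res.predict(X_new)
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        learners: Sequence[LearnerSpec] | None = None,
        schemes: Sequence[CombinationScheme] | None = None,
        meta_learner: LearnerSpec | None = None,
        k_meta: int = 3,
        n_folds: int = 10,
        seed: int = 0,
    ) -> None:
        super().__init__(X, y, learners, meta_learner, n_folds, seed)
        self.schemes = list(schemes) if schemes is not None else default_schemes()
        if k_meta < 0 or k_meta > self.X.shape[1]:
            raise ValueError(f"k_meta must be in [0, n_features={self.X.shape[1]}]")
        self.k_meta = k_meta

    @classmethod
    def from_dataframe(cls, df, outcome: str = "outcome", **kwargs) -> "TieredStacking":
        ycol = df[outcome]
        y = ycol.map({"PTB": 1, "TB": 0, 1: 1, 0: 0}).to_numpy()
        X = df.drop(columns=[outcome]).to_numpy(dtype=float)
        return cls(X, y, **kwargs)

    def fit(self) -> "TieredStackingResults":
        folds, oof, fitted = self._base_tier()
        meta_X = build_meta_features(oof, self.schemes)
        if self.k_meta > 0:
            ranking = rank_by_correlation(self.X, self.y)
            selected = select_top_k(ranking, self.k_meta)
            level1 = np.hstack([meta_X, self.X[:, selected]])
        else:
            selected = []
            level1 = meta_X
        meta_est = make_learner(self.meta_learner, seed=self.seed)
        meta_est.fit(level1, self.y)
        return TieredStackingResults(
            model=self,
            variant="tiered",
            base_learners=fitted,
            schemes=self.schemes,
            selected_features=list(selected),
            meta_estimator=meta_est,
            fold_plan=folds,
            oof=oof,
            level1_columns=[s.identifier for s in self.schemes]
            + [f"x{j}" for j in selected],
        )


class TraditionalStacking(_StackingBase):
    """Traditional stacked ensemble (SE) baseline.

    The meta-learner trains directly on the n x m matrix of OOF base-learner
    scores — no combination schemes, no appended raw features. Shares fold
    plans with :class:`TieredStacking` under the same seed, so the two can
    be compared on paired splits.
    """

    def fit(self) -> "TieredStackingResults":
        folds, oof, fitted = self._base_tier()
        meta_est = make_learner(self.meta_learner, seed=self.seed)
        meta_est.fit(oof.scores, self.y)
        return TieredStackingResults(
            model=self,
            variant="traditional",
            base_learners=fitted,
            schemes=[],
            selected_features=[],
            meta_estimator=meta_est,
            fold_plan=folds,
            oof=oof,
            level1_columns=[spec.identifier for spec in self.learners],
        )


@dataclass
class TieredStackingResults:
    """Fitted stacked-ensemble artifact.

    Carries the refit base learners, the scheme list, the selected raw
    feature indices, the fitted meta-learner, and the training-time fold
    plan / OOF predictions for diagnostics.
    """

    model: _StackingBase
    variant: str  # "tiered" | "traditional"
    base_learners: list[BaseEstimator]
    schemes: list[CombinationScheme]
    selected_features: list[int]
    meta_estimator: BaseEstimator
    fold_plan: FoldPlan
    oof: OOFPredictions
    level1_columns: list[str]

    def _level1(self, Xnew: np.ndarray) -> np.ndarray:
        Xnew = np.asarray(Xnew, dtype=float)
        if Xnew.ndim != 2 or Xnew.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"expected {self.model.X.shape[1]} feature columns, got "
                f"{Xnew.shape[1] if Xnew.ndim == 2 else 'non-2d input'}"
            )
        base_scores = np.column_stack([_score(est, Xnew) for est in self.base_learners])
        if self.variant == "traditional":
            return base_scores
        oof_like = OOFPredictions(
            scores=base_scores, labels=(base_scores >= 0.5).astype(int)
        )
        meta = build_meta_features(oof_like, self.schemes)
        if self.selected_features:
            meta = np.hstack([meta, Xnew[:, self.selected_features]])
        return meta

    def predict(self, Xnew: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """PTB scores in [0, 1] and hard labels (score >= 0.5)."""
        level1 = self._level1(Xnew)
        scores = _score(self.meta_estimator, level1)
        return scores, (scores >= 0.5).astype(int)

    def predict_scores(self, Xnew: np.ndarray) -> np.ndarray:
        return self.predict(Xnew)[0]

    def summary(self) -> str:
        """Human-readable description of the fitted ensemble."""
        lines = [
            f"{'Tiered stacked ensemble' if self.variant == 'tiered' else 'Traditional stacked ensemble (SE)'}",
            "=" * 46,
            f"training instances : {self.model.X.shape[0]}",
            f"features           : {self.model.X.shape[1]}",
            f"base learners (m)  : {len(self.base_learners)} "
            f"[{', '.join(s.identifier for s in self.model.learners)}]",
        ]
        if self.variant == "tiered":
            lines += [
                f"schemes (s)        : {len(self.schemes)} "
                f"[{', '.join(s.identifier for s in self.schemes)}]",
                f"appended features  : {self.selected_features}",
            ]
        lines += [
            f"meta-learner       : {self.model.meta_learner.identifier}",
            f"level-1 columns    : {len(self.level1_columns)} {self.level1_columns}",
            f"cv folds / seed    : {self.fold_plan.n_folds} / {self.model.seed}",
            "OOF mean score by learner: "
            + ", ".join(f"{v:.3f}" for v in self.oof.scores.mean(axis=0)),
        ]
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path, preprocessor=None) -> None:
        """Serialize the fitted artifact (optionally with its preprocessor)."""
        joblib.dump(
            {"format_version": SERIAL_FORMAT_VERSION, "results": self, "preprocessor": preprocessor},
            path,
        )

    @staticmethod
    def load(path: str | Path) -> tuple["TieredStackingResults", object]:
        payload = joblib.load(path)
        if payload.get("format_version") != SERIAL_FORMAT_VERSION:
            raise ValueError(f"unsupported model file version: {payload.get('format_version')}")
        return payload["results"], payload.get("preprocessor")


# ---------------------------------------------------------------------------
# Functional wrappers


def fit_tiered_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    learners: Sequence[LearnerSpec] | None = None,
    schemes: Sequence[CombinationScheme] | None = None,
    meta: LearnerSpec | None = None,
    k_meta: int = 3,
    n_folds: int = 10,
    seed: int = 0,
) -> TieredStackingResults:
    """Fit the three-tier stacked ensemble (convenience wrapper)."""
    return TieredStacking(
        X, y, learners=learners, schemes=schemes, meta_learner=meta,
        k_meta=k_meta, n_folds=n_folds, seed=seed,
    ).fit()


def fit_traditional_se(
    X: np.ndarray,
    y: np.ndarray,
    learners: Sequence[LearnerSpec] | None = None,
    meta: LearnerSpec | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> TieredStackingResults:
    """Fit the traditional stacked-ensemble baseline (convenience wrapper)."""
    return TraditionalStacking(
        X, y, learners=learners, meta_learner=meta, n_folds=n_folds, seed=seed,
    ).fit()
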