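"""Correlation-based feature ranking and top-k selection.

Features are ranked by the absolute Pearson product-moment correlation of
each column with the class label. For a binary feature against a binary
label this is the phi coefficient, so one code path serves both binary and
numeric columns. The top-3 ranked features feed the generalization tier;
the top-5 feed the outlier screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureRanking", "rank_by_correlation", "select_top_k"]


@dataclass(frozen=True)
class FeatureRanking:
    """Ordered (feature_index, |correlation|) pairs, scores non-increasing.

    Ties are broken by ascending feature index. Constant columns score 0.
    """

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(a < b - 1e-15 for a, b in zip(scores, scores[1:])):
            raise ValueError("ranking scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def indices(self) -> list[int]:
        return [j for j, _ in self.entries]

    def scores(self) -> list[float]:
        return [s for _, s in self.entries]


def rank_by_correlation(X: np.ndarray, y: np.ndarray) -> FeatureRanking:
    """Rank features by |Pearson correlation| with the label, descending.

    Parameters
    ----------
    X : (n, p) ndarray
        Complete (no-missing) feature matrix.
    y : (n,) ndarray
        Binary labels; both classes must be present.

    Notes
    -----
    For binary columns the score equals the phi coefficient
    ``(ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d))`` of the 2x2 contingency
    table. Columns with zero variance are assigned score 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) aligned with y")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 instances")
    if np.unique(y).size < 2:
        raise ValueError("labels are single-class; correlation undefined")

    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    num = Xc.T @ yc
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    scores = np.abs(r)
    order = sorted(range(X.shape[1]), key=lambda j: (-scores[j], j))
    return FeatureRanking(tuple((j, float(scores[j])) for j in order))


def select_top_k(ranking: FeatureRanking, k: int) -> list[int]:
    """First ``k`` feature indices of the ranking, order preserved."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds number of ranked features ({len(ranking)})")
    return ranking.indices()[:k]
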