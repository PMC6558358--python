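"""Synthetic preterm-birth risk-factor data generator.

Emulates the structure of a masked obstetric registry: mostly binary risk
factors split into primary (critical clinical indicators, large effects)
and secondary (behavioral/social, small effects) tiers, a class
distribution skewed toward term birth (PTB is the minority), sporadic
missing cells, and a guaranteed mix of all four patient cases — (any
primary risk factor present or absent) x (PTB or TB).

The label model is a latent logistic: each factor is an independent
Bernoulli draw, P(PTB) = logistic(intercept + sum_j w_j x_j), labels are
Bernoulli of that probability and then flipped with a small label-noise
rate so that achievable accuracy plateaus below 100%, as in real registry
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FeatureMeta, RiskFactorDataset, PRIMARY, SECONDARY

__all__ = ["GeneratorConfig", "generate", "generate_separable", "expected_prevalence"]


def _descending(hi: float, lo: float, k: int) -> tuple[float, ...]:
    return tuple(np.linspace(hi, lo, k))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic risk-factor registry.

    Defaults give 2,600 patients, 8 primary + 12 secondary binary factors,
    per-factor prevalences between 5% and 30%, log-odds effects of 1.5
    down to 0.4 for primary factors and 0.3 down to 0.05 for secondary
    ones, an intercept of -2.2 (PTB prevalence ~= 20%, comfortably the
    minority class), 2% label noise and 1% missing cells.
    """

    n: int = 2600
    n_primary: int = 8
    n_secondary: int = 12
    primary_weights: tuple[float, ...] = field(default_factory=lambda: _descending(1.5, 0.4, 8))
    secondary_weights: tuple[float, ...] = field(default_factory=lambda: _descending(0.3, 0.05, 12))
    intercept: float = -2.2
    factor_prevalences: tuple[float, ...] | None = None  # None -> per-block default
    label_noise: float = 0.02
    missing_rate: float = 0.01
    seed: int = 0

    def resolved_prevalences(self) -> np.ndarray:
        # default rule: within each criticality block, prevalence declines
        # with effect size from 20% down to 5% — the strong clinical factors
        # are the moderately common ones, the weak ones are rare
        if self.factor_prevalences is None:
            return np.concatenate(
                [
                    np.linspace(0.20, 0.05, self.n_primary),
                    np.linspace(0.20, 0.05, self.n_secondary),
                ]
            )
        return np.asarray(self.factor_prevalences, dtype=float)

    @property
    def n_features(self) -> int:
        return self.n_primary + self.n_secondary

    def validate(self) -> None:
        if self.n_primary < 1 or self.n_secondary < 1:
            raise ValueError("need at least one primary and one secondary factor")
        if len(self.primary_weights) != self.n_primary:
            raise ValueError("primary_weights length must equal n_primary")
        if len(self.secondary_weights) != self.n_secondary:
            raise ValueError("secondary_weights length must equal n_secondary")
        if min(self.primary_weights) <= max(self.secondary_weights):
            raise ValueError("every primary weight must exceed every secondary weight")
        prev = self.resolved_prevalences()
        if len(prev) != self.n_features:
            raise ValueError("factor_prevalences length must equal total factor count")
        for name, v in [("factor prevalence", prev.min()), ("factor prevalence", prev.max()),
                        ("label_noise", self.label_noise), ("missing_rate", self.missing_rate)]:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _metadata(config: GeneratorConfig) -> list[FeatureMeta]:
    meta = [
        FeatureMeta(name=f"primary_{i + 1:02d}", criticality=PRIMARY, dtype="binary",
                    default_value=0)
        for i in range(config.n_primary)
    ]
    meta += [
        FeatureMeta(name=f"secondary_{i + 1:02d}", criticality=SECONDARY, dtype="binary",
                    default_value=0)
        for i in range(config.n_secondary)
    ]
    return meta


def generate(config: GeneratorConfig | None = None) -> RiskFactorDataset:
    """Draw a synthetic risk-factor dataset from the latent logistic model.

    Guarantees that all four (any-primary-factor x label) patient cases are
    present, redrawing labels up to 100 times if a case is missing; raises
    if the mix is unattainable (e.g. a degenerate intercept drives every
    label to one class). Missing cells are injected at ``missing_rate``
    into features only — never into the label.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    prev = config.resolved_prevalences()
    X = (rng.uniform(size=(config.n, config.n_features)) < prev).astype(float)
    w = np.asarray(config.primary_weights + config.secondary_weights)
    p_ptb = 1.0 / (1.0 + np.exp(-(config.intercept + X @ w)))

    any_primary = X[:, : config.n_primary].any(axis=1)
    y = None
    for _ in range(100):
        draw = (rng.uniform(size=config.n) < p_ptb).astype(int)
        flips = rng.uniform(size=config.n) < config.label_noise
        draw[flips] = 1 - draw[flips]
        cases = {(bool(a), int(l)) for a, l in zip(any_primary, draw)}
        if len(cases) == 4:
            y = draw
            break
    if y is None:
        raise RuntimeError(
            "could not realize all four (risk-factor x outcome) cases in 100 label draws; "
            "check the generator configuration"
        )

    if config.missing_rate > 0:
        miss = rng.uniform(size=X.shape) < config.missing_rate
        X[miss] = np.nan

    return RiskFactorDataset(X=X, y=y, meta=_metadata(config))


def generate_separable(n: int, seed: int = 0) -> RiskFactorDataset:
    """Noise-free fixture: label = OR of the first two primary factors.

    No label noise, no missing cells — a decision tree separates it
    perfectly, which makes held-out accuracy 1.0 the expected outcome for
    any sensible ensemble. Used in exactness tests.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    config = GeneratorConfig(n=n, seed=seed, label_noise=0.0, missing_rate=0.0)
    rng = np.random.default_rng(seed)
    # prevalences ~0.35 on the two label-driving factors keep both classes frequent
    prev = np.full(config.n_features, 0.15)
    prev[:2] = 0.35
    X = (rng.uniform(size=(n, config.n_features)) < prev).astype(float)
    y = np.logical_or(X[:, 0] == 1, X[:, 1] == 1).astype(int)
    return RiskFactorDataset(X=X, y=y, meta=_metadata(config))


def expected_prevalence(config: GeneratorConfig, n_mc: int = 50_000, seed: int = 12345) -> float:
    """Monte-Carlo estimate of the model-implied P(PTB) under the config.

    Independent of :func:`generate`; used as an oracle for prevalence
    control checks.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    prev = config.resolved_prevalences()
    X = (rng.uniform(size=(n_mc, config.n_features)) < prev).astype(float)
    w = np.asarray(config.primary_weights + config.secondary_weights)
    p = 1.0 / (1.0 + np.exp(-(config.intercept + X @ w)))
    # label noise shifts prevalence toward 0.5: p' = p(1-e) + (1-p)e
    p_noisy = p * (1 - config.label_noise) + (1 - p) * config.label_noise
    return float(p_noisy.mean())
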