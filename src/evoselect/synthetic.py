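"""Synthetic tabular data with planted ground truth.

Emulates the statistical shape of a multi-instrument biobehavioral
battery: ~160 mixed-provenance continuous features of which only a
sparse subset is informative, correlated near-duplicate features
(instruments measuring the same construct), skewed marginals,
per-feature missingness up to ~50%, and class imbalance for
classification targets.  The generator returns the ground-truth
informative features so recovery can be measured, and a brute-force
best-subset oracle is provided for small feature pools.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .fitness import bic_classification, bic_regression

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "oracle_best_subset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Defaults mirror the target study shape: ~1000 participants by 160
    continuous features with a sparse informative subset, redundant
    correlated copies, skewed marginals, per-feature missingness drawn
    uniformly up to ``missing_fraction``, and (for classification) a
    case fraction of ``class_balance``.
    """

    n_samples: int = 1000
    n_features: int = 160
    n_informative: int = 8
    effect_sizes: tuple[float, ...] | None = None  # default: all 1.0
    interaction_pairs: tuple[tuple[int, int], ...] = ()
    noise_sd: float = 0.5
    n_redundant: int = 16
    redundant_noise_frac: float = 0.1  # noise sd as a fraction of parent sd
    skewed_fraction: float = 0.3
    missing_fraction: float = 0.0  # max per-feature MCAR rate (<= 0.5)
    task: str = "regression"
    class_balance: float = 0.3  # requested case fraction, in (0, 1]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_features:
            raise ConfigurationError(
                "n_informative + n_redundant must be <= n_features"
            )
        if self.n_informative < 1:
            raise ConfigurationError("need at least 1 informative feature")
        if not 0 < self.class_balance <= 1:
            raise ConfigurationError("class_balance must be in (0, 1]")
        if not 0 <= self.missing_fraction <= 0.5:
            raise ConfigurationError("missing_fraction must be in [0, 0.5]")
        if self.effect_sizes is not None and len(self.effect_sizes) != self.n_informative:
            raise ConfigurationError("effect_sizes length must equal n_informative")

    @property
    def effects(self) -> np.ndarray:
        if self.effect_sizes is None:
            return np.ones(self.n_informative)
        return np.asarray(self.effect_sizes, dtype=float)


@dataclass(frozen=True)
class GroundTruth:
    informative_features: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float = 0.0


def _feature_names(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"f{i:0{width}d}" for i in range(n)]


def _tune_intercept(signal: np.ndarray, target_fraction: float) -> float:
    """Bisection on the logistic intercept so the expected case fraction
    matches the request within +/- 2%."""

    def frac(b: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(signal + b)))))

    lo, hi = -50.0, 50.0
    if not frac(lo) <= target_fraction <= frac(hi):
        raise ConfigurationError(
            f"requested case fraction {target_fraction} unattainable"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target_fraction:
            lo = mid
        else:
            hi = mid
    b = 0.5 * (lo + hi)
    if abs(frac(b) - target_fraction) > 0.02:
        raise ConfigurationError("intercept bisection failed to converge")
    return b


def generate(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, np.ndarray, GroundTruth]:
    """Draw one dataset; returns (features, target, ground truth).

    The target is a linear combination of the informative features (plus
    any pairwise interactions) with Gaussian noise; for classification
    labels come through a logistic link whose intercept is tuned by
    bisection to the requested case fraction.  Redundant features are
    noisy copies of informative ones; a fraction of the remaining noise
    features is exponentiated to produce skewed marginals; missing cells
    are MCAR with per-feature rates drawn up to ``missing_fraction``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_features
    names = _feature_names(m)
    X = rng.standard_normal((n, m))

    info = np.arange(spec.n_informative)
    signal = X[:, info] @ spec.effects
    for i, j in spec.interaction_pairs:
        signal = signal + X[:, i] * X[:, j]

    # redundant features: noisy copies of informative parents (cyclic)
    for r in range(spec.n_redundant):
        parent = info[r % spec.n_informative]
        col = spec.n_informative + r
        X[:, col] = X[:, parent] + spec.redundant_noise_frac * rng.standard_normal(n)

    # skew a fraction of the pure-noise features so marginals are realistic
    noise_cols = np.arange(spec.n_informative + spec.n_redundant, m)
    n_skew = int(round(spec.skewed_fraction * len(noise_cols)))
    for col in noise_cols[:n_skew]:
        X[:, col] = np.exp(X[:, col])

    intercept = 0.0
    if spec.task == "classification":
        intercept = _tune_intercept(signal, spec.class_balance)
        prob = 1.0 / (1.0 + np.exp(-(signal + intercept)))
        y = (rng.uniform(size=n) < prob).astype(int)
        if y.min() == y.max():
            raise ConfigurationError(
                f"case fraction {spec.class_balance} produced a single class"
            )
    else:
        y = signal + spec.noise_sd * rng.standard_normal(n)

    if spec.missing_fraction > 0:
        rates = rng.uniform(0, spec.missing_fraction, size=m)
        drop = rng.uniform(size=(n, m)) < rates
        X = np.where(drop, np.nan, X)

    truth = GroundTruth(
        informative_features=tuple(names[i] for i in info),
        coefficients=tuple(float(e) for e in spec.effects),
        intercept=intercept,
    )
    return pd.DataFrame(X, columns=names), y, truth


def oracle_best_subset(
    X: pd.DataFrame,
    y,
    task: str = "regression",
    scorer=None,
    max_pool: int = 15,
) -> dict:
    """Exhaustive best-subset search by BIC over every non-empty subset.

    The independent enumeration oracle for evolutionary runs on small
    pools.  By default each subset is scored with an ordinary
    least-squares (or logistic) fit and the same BIC convention the
    fitness module uses (``p = |subset| + 1``); pass ``scorer(features)
    -> bic`` to score with a different evaluation protocol.  Refuses
    pools larger than ``max_pool`` (combinatorial guard).
    """
    cols = list(X.columns)
    if len(cols) > max_pool:
        raise ConfigurationError(
            f"{len(cols)} features exceeds the exhaustive-search guard ({max_pool})"
        )
    y = np.asarray(y)
    n = len(y)

    if scorer is None:
        values = X.to_numpy(dtype=float)

        if task == "regression":
            def scorer(feats):
                idx = [cols.index(f) for f in feats]
                A = np.column_stack([np.ones(n), values[:, idx]])
                beta, *_ = np.linalg.lstsq(A, y, rcond=None)
                return bic_regression(y, A @ beta, len(feats) + 1)
        else:
            from sklearn.linear_model import LogisticRegression

            def scorer(feats):
                idx = [cols.index(f) for f in feats]
                model = LogisticRegression(penalty=None, max_iter=1000)
                model.fit(values[:, idx], y)
                prob = model.predict_proba(values[:, idx])
                return bic_classification(y, prob, len(feats) + 1)

    best_feats, best_bic = None, np.inf
    scores = {}
    for size in range(1, len(cols) + 1):
        for subset in itertools.combinations(cols, size):
            bic = float(scorer(list(subset)))
            scores[subset] = bic
            if bic < best_bic:
                best_feats, best_bic = subset, bic
    return {
        "best_features": tuple(best_feats),
        "best_bic": best_bic,
        "n_subsets": len(scores),
        "scores": scores,
    }
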