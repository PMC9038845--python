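"""Chromosome fitness: adaptive k-fold CV and the BIC fitness value.

Each candidate model is scored by cross-validating the inner learner on
the candidate's selected features.  The number of splits adapts to the
candidate: ``k = ceil(n_samples / n_features)``, so small feature sets
get many folds (approaching leave-one-out) and large ones few; an
optional cap keeps desk-scale runs affordable.  Folds are stratified for
classification.  The fitness is the Bayes Information Criterion computed
on the pooled out-of-fold predictions (lower is better):

* regression      — ``n * ln(SSE / n) + p * ln(n)`` (Gaussian residuals),
* classification  — ``-2 * sum_i ln p_hat_i(y_i) + p * ln(n)`` (Bernoulli
  log-likelihood on clipped probabilities),

with ``p = |selected features| + 1`` (an intercept; non-evolved settings
are not counted as parameters).  Degenerate likelihoods are clipped at
``1e-12`` so the fitness is always finite; a failed inner fit yields a
``+inf`` sentinel instead of aborting the evolutionary run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import (
    accuracy_score,
    explained_variance_score,
    mean_squared_error,
    precision_score,
    r2_score,
    recall_score,
)
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import EvaluationError
from .inner_models import CLASSIFICATION, REGRESSION, make_inner_model
from .search_space import Chromosome

__all__ = [
    "EvaluatedModel",
    "adaptive_k",
    "crossval_predict",
    "bic_regression",
    "bic_classification",
    "evaluate",
    "Evaluator",
]

EPS = 1e-12


@dataclass
class EvaluatedModel:
    """A chromosome together with its cross-validated scorecard."""

    chromosome: Chromosome
    bic: float
    metrics: dict[str, float]
    importances: dict[str, float]
    n_folds_used: int
    failed: bool = False

    @property
    def n_features(self) -> int:
        return len(self.chromosome.features)

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome.to_dict(),
            "bic": self.bic,
            "metrics": dict(self.metrics),
            "importances": {k: self.importances[k] for k in sorted(self.importances)},
            "n_folds_used": self.n_folds_used,
            "failed": self.failed,
        }


def adaptive_k(
    n_samples: int,
    n_features: int,
    k_min: int = 2,
    k_cap: int | None = None,
) -> int:
    """Number of CV splits: ``ceil(n_samples / n_features)``, clamped.

    The lower clamp is ``max(2, k_min)``; the upper clamp is
    ``min(n_samples, k_cap)`` when a cap is given, else ``n_samples``.
    """
    if n_samples < 2:
        raise EvaluationError(f"need at least 2 samples, got {n_samples}")
    if n_features < 1:
        raise EvaluationError("need at least 1 feature")
    k = math.ceil(n_samples / n_features)
    k = max(k, max(2, k_min))
    upper = n_samples if k_cap is None else min(n_samples, k_cap)
    return min(k, upper)


def crossval_predict(
    inner,
    X,
    y,
    task: str,
    k: int,
    rng: np.random.Generator,
):
    """Pooled out-of-fold predictions from k-fold CV.

    Returns ``(predictions, n_folds_used)``.  For regression the
    predictions are a vector; for classification a ``(n, n_classes)``
    probability matrix with columns ordered by sorted class label.
    Stratified folds are used for classification; if a class cannot be
    represented in every training fold, k is reduced by 1 and the CV
    refit, down to k = 2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    seed = int(rng.integers(2**31))

    if task == CLASSIFICATION:
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise EvaluationError("classification target has a single class")
        # each fold's training part must contain every class
        k = min(k, int(counts.min()))
        if k < 2:
            raise EvaluationError(
                "minority class too small for 2-fold stratified CV"
            )
        while True:
            try:
                splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
                probs = np.full((n, len(classes)), np.nan)
                for train_idx, test_idx in splitter.split(X, y):
                    model = clone(inner).fit(X[train_idx], y[train_idx])
                    p = model.predict_proba(X[test_idx])
                    # map the model's class order onto sorted global order
                    order = np.searchsorted(classes, model.classes_)
                    probs[np.ix_(test_idx, order)] = p
                break
            except ValueError:
                if k <= 2:
                    raise EvaluationError("stratified CV failed at k = 2")
                k -= 1
        return probs, k

    k = min(k, n)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.full(n, np.nan)
    for train_idx, test_idx in splitter.split(X):
        model = clone(inner).fit(X[train_idx], y[train_idx])
        preds[test_idx] = model.predict(X[test_idx])
    return preds, k


def bic_regression(y, y_hat, p: int) -> float:
    """Gaussian-residual BIC: ``n * ln(max(SSE/n, eps)) + p * ln(n)``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise EvaluationError("y and y_hat lengths differ")
    n = len(y)
    if n < 2:
        raise EvaluationError("need n >= 2")
    if p < 1:
        raise EvaluationError("need p >= 1")
    sse = float(np.sum((y - y_hat) ** 2))
    return n * math.log(max(sse / n, EPS)) + p * math.log(n)


def bic_classification(y, prob, p: int) -> float:
    """Bernoulli/multinomial BIC: ``-2 * sum ln p_hat(y) + p * ln(n)``.

    ``prob`` is either a vector of probabilities assigned to each
    sample's *observed* class, or an ``(n, n_classes)`` matrix with
    columns ordered by sorted class label.
    """
    y = np.asarray(y)
    prob = np.asarray(prob, dtype=float)
    n = len(y)
    if p < 1:
        raise EvaluationError("need p >= 1")
    if prob.ndim == 2:
        classes = np.unique(y)
        idx = np.searchsorted(classes, y)
        prob = prob[np.arange(n), idx]
    if prob.shape != (n,):
        raise EvaluationError("probability vector length mismatch")
    if np.any(prob < 0) or np.any(prob > 1):
        raise EvaluationError("probabilities outside [0, 1]")
    prob = np.clip(prob, EPS, 1 - EPS)
    return -2.0 * float(np.sum(np.log(prob))) + p * math.log(n)


def _classification_metrics(y, probs) -> dict[str, float]:
    classes = np.unique(y)
    y_hat = classes[np.argmax(probs, axis=1)]
    return {
        "accuracy": float(accuracy_score(y, y_hat)),
        "precision": float(precision_score(y, y_hat, zero_division=0)),
        "recall": float(recall_score(y, y_hat, zero_division=0)),
    }


def _regression_metrics(y, y_hat) -> dict[str, float]:
    return {
        "mse": float(mean_squared_error(y, y_hat)),
        "explained_variance": float(explained_variance_score(y, y_hat)),
        "r2": float(r2_score(y, y_hat)),
    }


def evaluate(
    chromosome: Chromosome,
    X: pd.DataFrame,
    y,
    task: str,
    inner_kind: str,
    rng: np.random.Generator,
    fixed_settings: dict | None = None,
    k_min: int = 2,
    k_cap: int | None = None,
    compute_importances: bool = True,
    perm_repeats: int = 5,
) -> EvaluatedModel:
    """Score one chromosome: CV predictions, metrics and BIC fitness.

    A failed inner fit is captured as a ``+inf``-fitness sentinel rather
    than raised, so the evolutionary loop survives pathological genes.
    """
    features = sorted(chromosome.features)
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(
            np.asarray(X, dtype=float),
            columns=[f"f{i:03d}" for i in range(np.asarray(X).shape[1])],
        )
    X_sub = X[features]
    y = np.asarray(y)
    p = len(features) + 1
    seed = int(rng.integers(2**31))
    inner = make_inner_model(
        inner_kind,
        task,
        chromosome.hyperparameter_values,
        fixed_settings,
        random_state=seed,
    )
    try:
        k = adaptive_k(len(y), len(features), k_min=k_min, k_cap=k_cap)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            preds, k_used = crossval_predict(inner, X_sub, y, task, k, rng)
            if task == CLASSIFICATION:
                metrics = _classification_metrics(y, preds)
                bic = bic_classification(y, preds, p)
            else:
                metrics = _regression_metrics(y, preds)
                bic = bic_regression(y, preds, p)
            importances: dict[str, float] = {}
            if compute_importances:
                fitted = clone(inner).fit(np.asarray(X_sub, dtype=float), y)
                if inner_kind == "net":
                    vals = fitted.feature_importances(
                        X_sub, y, rng=rng, repeats=perm_repeats
                    )
                else:
                    vals = fitted.feature_importances()
                importances = {f: float(v) for f, v in zip(features, vals)}
        return EvaluatedModel(chromosome, float(bic), metrics, importances, k_used)
    except Exception:
        return EvaluatedModel(chromosome, math.inf, {}, {}, 0, failed=True)


@dataclass
class Evaluator:
    """Callable binding a dataset and inner-model handle to ``evaluate``.

    The evolutionary loop only sees ``evaluator(chromosome, rng)``.
    """

    X: pd.DataFrame
    y: np.ndarray
    task: str
    inner_kind: str
    fixed_settings: dict = field(default_factory=dict)
    k_min: int = 2
    k_cap: int | None = None
    compute_importances: bool = True
    perm_repeats: int = 5

    def __call__(self, chromosome: Chromosome, rng: np.random.Generator) -> EvaluatedModel:
        return evaluate(
            chromosome,
            self.X,
            self.y,
            self.task,
            self.inner_kind,
            rng,
            fixed_settings=self.fixed_settings,
            k_min=self.k_min,
            k_cap=self.k_cap,
            compute_importances=self.compute_importances,
            perm_repeats=self.perm_repeats,
        )
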