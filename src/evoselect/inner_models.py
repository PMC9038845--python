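"""Adapters giving the three inner learners one uniform contract.

Every adapter is a scikit-learn estimator (``fit``/``predict``, plus
``predict_proba`` for classification) parameterized directly by the genes
of a chromosome, and exposes ``feature_importances(X, y, rng)`` after
fitting:

* linear elastic net   — signed coefficients (rank by magnitude);
* gradient-boosted trees — the ensemble's native gain importances;
* feedforward network  — permutation importance (performance drop when a
  column is shuffled), the model-agnostic route that makes the network
  explainable in terms of its original input features.

Architecture (layers/width), early-stopping patience, ensemble size and
the like are *fixed settings*, not genes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.linear_model import ElasticNet, LinearRegression, LogisticRegression
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .exceptions import ConfigurationError
from .search_space import Chromosome

__all__ = [
    "ElasticNetModel",
    "GradientBoostedTreesModel",
    "FeedforwardNetModel",
    "make_inner_model",
    "permutation_importance",
]

CLASSIFICATION = "classification"
REGRESSION = "regression"


def _check_task(task: str) -> None:
    if task not in (CLASSIFICATION, REGRESSION):
        raise ConfigurationError(f"unknown task {task!r}")


class ElasticNetModel(BaseEstimator):
    """Elastic-net linear model with independent L1 and L2 penalty genes.

    The genes are the L1 and L2 penalty weights in [0, 1] applied
    directly to the coefficient norms.  scikit-learn parameterizes the
    penalty as ``alpha * (l1_ratio * ||w||_1 + (1 - l1_ratio)/2 * ...)``;
    the bijection used is ``alpha = l1 + l2`` and
    ``l1_ratio = l1 / (l1 + l2)`` (inverse: ``l1 = alpha * l1_ratio``,
    ``l2 = alpha * (1 - l1_ratio)``), with the unpenalized model at
    ``l1 = l2 = 0``.  Importance of feature j is its fitted coefficient
    (signed; rank by absolute value).
    """

    kind = "linear"

    def __init__(
        self,
        l1_penalty: float = 0.15,
        l2_penalty: float = 0.15,
        task: str = REGRESSION,
        max_iter: int = 2000,
        random_state: int | None = None,
    ):
        self.l1_penalty = l1_penalty
        self.l2_penalty = l2_penalty
        self.task = task
        self.max_iter = max_iter
        self.random_state = random_state

    def _build(self):
        _check_task(self.task)
        if not (0 <= self.l1_penalty and 0 <= self.l2_penalty):
            raise ConfigurationError("penalties must be >= 0")
        total = self.l1_penalty + self.l2_penalty
        if self.task == REGRESSION:
            if total == 0:
                return LinearRegression()
            return ElasticNet(
                alpha=total,
                l1_ratio=self.l1_penalty / total,
                max_iter=self.max_iter,
                random_state=self.random_state,
            )
        if total == 0:
            return LogisticRegression(C=np.inf, max_iter=self.max_iter)
        return LogisticRegression(
            solver="saga",
            C=1.0 / total,
            l1_ratio=self.l1_penalty / total,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y.astype(float)))):
            raise ValueError("non-finite values in input")
        self.model_ = self._build()
        self.model_.fit(X, y)
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    @property
    def classes_(self):
        return self.model_.classes_

    def feature_importances(self, X=None, y=None, rng=None) -> np.ndarray:
        coef = self.model_.coef_
        return np.ravel(coef)


class GradientBoostedTreesModel(BaseEstimator):
    """Gradient-boosted decision-tree ensemble (xgboost, gbtree booster).

    Genes: maximum tree depth, node-partition threshold (gamma) and L1
    penalty (alpha).  The ensemble size is a fixed setting (100 rounds).
    Importances are the ensemble's native gain-based importances.
    """

    kind = "tree"

    def __init__(
        self,
        max_depth: int = 6,
        gamma: float = 0.0,
        alpha: float = 0.0,
        task: str = REGRESSION,
        n_estimators: int = 100,
        random_state: int | None = None,
    ):
        self.max_depth = max_depth
        self.gamma = gamma
        self.alpha = alpha
        self.task = task
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _build(self):
        _check_task(self.task)
        depth = int(self.max_depth)
        if not 2 <= depth <= 10:
            raise ConfigurationError(f"max_depth {depth} outside [2, 10]")
        if self.gamma < 0 or self.alpha < 0:
            raise ConfigurationError("gamma and alpha must be >= 0")
        from xgboost import XGBClassifier, XGBRegressor

        cls = XGBClassifier if self.task == CLASSIFICATION else XGBRegressor
        return cls(
            booster="gbtree",
            max_depth=depth,
            gamma=self.gamma,
            reg_alpha=self.alpha,
            n_estimators=self.n_estimators,
            importance_type="gain",
            n_jobs=1,
            random_state=0 if self.random_state is None else self.random_state,
            verbosity=0,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.model_ = self._build()
        self.model_.fit(X, np.asarray(y))
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    @property
    def classes_(self):
        return self.model_.classes_

    def feature_importances(self, X=None, y=None, rng=None) -> np.ndarray:
        return np.asarray(self.model_.feature_importances_, dtype=float)


class FeedforwardNetModel(BaseEstimator):
    """Fully connected feedforward network trained with Adam.

    Genes: learning rate and the Adam decay rates beta1/beta2.  Fixed
    settings: rectified-linear hidden activations, 3 layers of 300
    neurons by default (configurable down to desk scale for tests),
    early stopping on the loss of an internal 10% validation split with
    patience 3, softmax output for classification.  Fits are
    deterministic given ``random_state``.
    """

    kind = "net"

    def __init__(
        self,
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        task: str = REGRESSION,
        hidden_layer_sizes: tuple[int, ...] = (300, 300, 300),
        patience: int = 3,
        validation_fraction: float = 0.1,
        max_iter: int = 200,
        batch_size: int | str = "auto",
        random_state: int | None = None,
    ):
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.task = task
        self.hidden_layer_sizes = hidden_layer_sizes
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.max_iter = max_iter
        self.batch_size = batch_size
        self.random_state = random_state

    def _build(self):
        _check_task(self.task)
        if not 0 < self.learning_rate:
            raise ConfigurationError("learning rate must be > 0")
        cls = MLPClassifier if self.task == CLASSIFICATION else MLPRegressor
        return cls(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            activation="relu",
            solver="adam",
            learning_rate_init=self.learning_rate,
            beta_1=self.beta1,
            beta_2=self.beta2,
            early_stopping=True,
            n_iter_no_change=self.patience,
            validation_fraction=self.validation_fraction,
            max_iter=self.max_iter,
            batch_size=self.batch_size,
            random_state=0 if self.random_state is None else self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.model_ = self._build()
        self.model_.fit(X, np.asarray(y))
        if not np.all(np.isfinite(self.model_.loss_curve_)):
            raise ValueError("training loss diverged (non-finite)")
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    @property
    def classes_(self):
        return self.model_.classes_

    def feature_importances(self, X, y, rng=None, repeats: int = 5) -> np.ndarray:
        """Permutation importances on the supplied evaluation set."""
        return permutation_importance(
            self,
            X,
            y,
            metric="accuracy" if self.task == CLASSIFICATION else "r2",
            repeats=repeats,
            rng=rng,
        )


_KINDS = {
    "linear": ElasticNetModel,
    "tree": GradientBoostedTreesModel,
    "net": FeedforwardNetModel,
}


def make_inner_model(
    kind: str,
    task: str,
    hyperparameter_values: dict[str, float] | Chromosome | None = None,
    fixed_settings: dict | None = None,
    random_state: int | None = None,
) -> BaseEstimator:
    """Build an unfitted adapter of ``kind`` from gene values.

    ``fixed_settings`` passes through non-evolved settings (architecture,
    ensemble size, iteration budgets).
    """
    if kind not in _KINDS:
        raise ConfigurationError(
            f"unknown inner-model kind {kind!r}; expected one of {sorted(_KINDS)}"
        )
    if isinstance(hyperparameter_values, Chromosome):
        hyperparameter_values = hyperparameter_values.hyperparameter_values
    params = dict(hyperparameter_values or {})
    params.update(fixed_settings or {})
    params.setdefault("task", task)
    params.setdefault("random_state", random_state)
    return _KINDS[kind](**params)


def permutation_importance(
    model,
    X,
    y,
    metric: str = "r2",
    repeats: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mean drop in ``metric`` when each column is shuffled in place.

    Importance of feature j is ``mean over repeats of
    [metric(baseline) - metric(column j shuffled)]``, shuffling only
    within the supplied evaluation set.
    """
    if repeats < 1:
        raise ConfigurationError("repeats must be >= 1")
    seed = int(rng.integers(2**31)) if rng is not None else 0
    scoring = {"accuracy": "accuracy", "r2": "r2"}[metric]
    result = _sk_permutation_importance(
        model,
        np.asarray(X, dtype=float),
        np.asarray(y),
        scoring=scoring,
        n_repeats=repeats,
        random_state=seed,
        n_jobs=1,
    )
    return np.asarray(result.importances_mean, dtype=float)


def clone_unfitted(model: BaseEstimator) -> BaseEstimator:
    """Fresh unfitted copy with identical settings."""
    return clone(model)
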