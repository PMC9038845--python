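"""Scikit-learn meta-estimator wrapping the full evolutionary search.

``EvolutionarySearch`` composes the standard phase and the optional
warm-start phase behind the familiar fit/predict surface, so it drops
into sklearn pipelines and model selection like any other estimator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .evolution import GenerationConfig, run_phase
from .exceptions import ConfigurationError
from .fitness import Evaluator
from .inner_models import CLASSIFICATION, REGRESSION, make_inner_model
from .search_space import build_space
from .warm_start import (
    aggregate_importance,
    elbow_points,
    find_elbow,
    make_plan,
    run_warm_start,
)

__all__ = ["EvolutionarySearch"]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{i:03d}" for i in range(X.shape[1])])


def _resolve_task(task: str, y) -> str:
    if task in (CLASSIFICATION, REGRESSION):
        return task
    if task != "auto":
        raise ConfigurationError(f"unknown task {task!r}")
    values = np.unique(np.asarray(y))
    return CLASSIFICATION if len(values) <= 2 else REGRESSION


class EvolutionarySearch(BaseEstimator):
    """Joint feature-subset and hyperparameter optimization by evolution.

    A population of candidate models — each a feature subset plus a
    hyperparameter vector for the chosen inner learner — is evolved by
    recombination, mutation, discard and random replenishment under a
    cross-validated BIC fitness until the fitness plateaus.  Optionally,
    a recursive warm-start phase reruns half-size evolution on feature
    pools constrained by aggregated importances at the elbow of the
    performance/feature-count curve.  The best model found is refit on
    the full training data.

    Parameters
    ----------
    inner : {'linear', 'tree', 'net'}
        Inner learner: elastic-net linear model, gradient-boosted trees,
        or feedforward network.
    task : {'auto', 'classification', 'regression'}
        'auto' infers classification for binary targets.
    n_population : int
        Base population n (100 in the reference configuration).
    subset_min, subset_max : int
        Feature-subset size bounds (subset_max clamped to the pool).
    max_generations : int
        Hard cap when the fitness never plateaus.
    plateau_window, plateau_tol : int, float
        Convergence: best fitness over the last ``plateau_window``
        generations must improve by less than ``plateau_tol`` (relative).
    warm_start_phase : bool
        Run the recursive constrained phase after the initial plateau.
    k_cap : int or None
        Optional cap on the adaptive CV split count (None reproduces the
        pure ceil(samples/features) rule; desk-scale runs use ~10).
    fixed_settings : dict or None
        Non-evolved inner-model settings (architecture, ensemble size).
    archive_size : int
        Number of best distinct models retained for validation and
        importance aggregation.

    Attributes
    ----------
    best_chromosome_ : Chromosome
        Lowest-BIC solution across all phases.
    best_estimator_ : fitted inner-model adapter
        The winning model refit on all training data.
    best_bic_ : float
    archive_ : list of EvaluatedModel
    importances_ : dict feature -> importance of the winning model
    result_, warm_result_ : phase run records
    n_generations_ : int (standard phase)
    """

    def __init__(
        self,
        inner: str = "linear",
        task: str = "auto",
        n_population: int = 100,
        subset_min: int = 1,
        subset_max: int = 50,
        max_generations: int = 500,
        plateau_window: int = 20,
        plateau_tol: float = 1e-4,
        warm_start_phase: bool = True,
        k_cap: int | None = None,
        fixed_settings: dict | None = None,
        archive_size: int = 100,
        perm_repeats: int = 5,
        random_state: int | None = None,
    ):
        self.inner = inner
        self.task = task
        self.n_population = n_population
        self.subset_min = subset_min
        self.subset_max = subset_max
        self.max_generations = max_generations
        self.plateau_window = plateau_window
        self.plateau_tol = plateau_tol
        self.warm_start_phase = warm_start_phase
        self.k_cap = k_cap
        self.fixed_settings = fixed_settings
        self.archive_size = archive_size
        self.perm_repeats = perm_repeats
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y)
        task = _resolve_task(self.task, y)
        rng = np.random.default_rng(self.random_state)
        space = build_space(
            self.inner, list(X.columns), self.subset_min, self.subset_max
        )
        evaluator = Evaluator(
            X,
            y,
            task,
            self.inner,
            fixed_settings=dict(self.fixed_settings or {}),
            k_cap=self.k_cap,
            perm_repeats=self.perm_repeats,
        )
        config = GenerationConfig(n=self.n_population)
        run_kwargs = dict(
            max_generations=self.max_generations,
            plateau_window=self.plateau_window,
            plateau_tol=self.plateau_tol,
            archive_size=self.archive_size,
        )
        self.result_ = run_phase(
            evaluator, space, config, rng, seed=self.random_state, **run_kwargs
        )
        self.n_generations_ = self.result_.n_generations
        self.archive_ = list(self.result_.archive)

        self.warm_result_ = None
        self.warm_plan_ = None
        if self.warm_start_phase:
            metric = "accuracy" if task == CLASSIFICATION else "r2"
            table = aggregate_importance(self.result_.archive)
            # elbow curve over every model evaluated during the run (the
            # best-distinct archive alone can collapse to one feature
            # count once a dominant feature set saturates breeding)
            points = sorted(self.result_.envelope.get(metric, {}).items())
            if len(points) >= 3 and len(table.ranked_features) >= 1:
                elbow = find_elbow(points)
                elbow = min(elbow, len(table.ranked_features))
                plan = make_plan(table, max(elbow, 1))
                self.warm_plan_ = plan
                winner, stages = run_warm_start(
                    evaluator, space, table, plan, config, rng, **run_kwargs
                )
                self.warm_result_ = winner
                self.warm_stages_ = stages
                merged = {id(m): m for m in self.archive_ + list(winner.archive)}
                self.archive_ = sorted(
                    merged.values(), key=lambda m: (m.bic, m.n_features)
                )[: self.archive_size]

        best = min(self.archive_, key=lambda m: (m.bic, m.n_features))
        self.best_model_ = best
        self.best_chromosome_ = best.chromosome
        self.best_bic_ = best.bic
        self.importances_ = dict(best.importances)
        self.task_ = task
        self.selected_features_ = sorted(best.chromosome.features)
        self.feature_names_in_ = np.asarray(X.columns)

        refit_seed = int(rng.integers(2**31))
        self.best_estimator_ = make_inner_model(
            self.inner,
            task,
            best.chromosome.hyperparameter_values,
            dict(self.fixed_settings or {}),
            random_state=refit_seed,
        ).fit(X[self.selected_features_].to_numpy(dtype=float), y)
        return self

    # ------------------------------------------------------------------
    def _subset(self, X) -> np.ndarray:
        X = _as_frame(X)
        return X[self.selected_features_].to_numpy(dtype=float)

    def predict(self, X):
        return self.best_estimator_.predict(self._subset(X))

    def predict_proba(self, X):
        if self.task_ != CLASSIFICATION:
            raise AttributeError("predict_proba is classification-only")
        return self.best_estimator_.predict_proba(self._subset(X))

    def score(self, X, y):
        """Accuracy for classification, R^2 for regression."""
        y = np.asarray(y)
        y_hat = self.predict(X)
        if self.task_ == CLASSIFICATION:
            return float(np.mean(y_hat == y))
        ss_res = float(np.sum((y - y_hat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
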