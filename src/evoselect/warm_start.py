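"""Recursive warm-start phase: importance thresholds and constrained reruns.

After the initial phase plateaus, per-feature importances are aggregated
over the archived best models and an elbow is located on the curve of
best performance vs. feature count.  The importance of the elbow-th
ranked feature becomes the base threshold; adding 0-4 standard
deviations of the (nonzero) aggregated importances yields a schedule of
five thresholds.  Each threshold constrains the feature pool to the
features at or above it and a fresh, half-population evolution run is
completed on that pool; the stage whose best model attains the lowest
fitness wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evolution import WARM_START, GenerationConfig, RunResult, run_phase
from .exceptions import ConfigurationError
from .fitness import EvaluatedModel
from .search_space import SearchSpace

__all__ = [
    "ImportanceTable",
    "WarmStartPlan",
    "aggregate_importance",
    "elbow_points",
    "find_elbow",
    "make_plan",
    "run_warm_start",
]


@dataclass(frozen=True)
class ImportanceTable:
    """Aggregated per-feature importances with a deterministic ranking."""

    importances: dict[str, float]
    ranked_features: tuple[str, ...]  # descending importance, ties by id

    def importance_of_rank(self, rank: int) -> float:
        """Importance of the ``rank``-th ranked feature (1-based)."""
        return self.importances[self.ranked_features[rank - 1]]


@dataclass(frozen=True)
class WarmStartPlan:
    """Elbow point and the five-threshold constraint schedule."""

    elbow_feature_count: int
    base_threshold: float
    sd: float
    thresholds: tuple[float, float, float, float, float]


def aggregate_importance(archive: list[EvaluatedModel]) -> ImportanceTable:
    """Per-feature mean of |importance| over archive models containing
    the feature; features selected by no archived model score 0."""
    if not archive:
        raise ConfigurationError("empty archive")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for model in archive:
        for f, v in model.importances.items():
            sums[f] = sums.get(f, 0.0) + abs(v)
            counts[f] = counts.get(f, 0) + 1
    importances = {f: sums[f] / counts[f] for f in sums}
    ranked = tuple(sorted(importances, key=lambda f: (-importances[f], f)))
    return ImportanceTable(importances, ranked)


def elbow_points(
    archive: list[EvaluatedModel], metric: str
) -> list[tuple[int, float]]:
    """Upper envelope of (feature count, best ``metric`` at that count)
    over the archived models, sorted by feature count."""
    best: dict[int, float] = {}
    for model in archive:
        if model.failed or metric not in model.metrics:
            continue
        c = model.n_features
        v = model.metrics[metric]
        if c not in best or v > best[c]:
            best[c] = v
    return sorted(best.items())


def find_elbow(points: list[tuple[int, float]]) -> int:
    """Feature count at the elbow of a performance-vs-count curve.

    Performance is oriented so larger is better.  The elbow is the point
    of the upper envelope (best performance per feature count) with the
    largest perpendicular distance to the chord joining the envelope's
    first and last points; if the envelope is affine (all distances
    below 1e-9) the smallest feature count is returned.  The location is
    invariant under affine rescaling of either axis.
    """
    env: dict[int, float] = {}
    for c, v in points:
        if c not in env or v > env[c]:
            env[c] = v
    if len(env) < 3:
        raise ConfigurationError("need >= 3 distinct feature counts")
    pts = sorted(env.items())
    counts = np.array([c for c, _ in pts], dtype=float)
    perf = np.array([v for _, v in pts], dtype=float)
    # normalize both axes so the distance is scale-free
    x = (counts - counts[0]) / (counts[-1] - counts[0])
    span = perf[-1] - perf[0]
    yv = (perf - perf[0]) / span if span != 0 else np.zeros_like(perf)
    dist = np.abs(yv - x) / np.sqrt(2.0)
    if np.all(dist < 1e-9):
        return int(counts[0])
    return int(counts[int(np.argmax(dist))])


def make_plan(table: ImportanceTable, elbow: int) -> WarmStartPlan:
    """Threshold schedule: importance of the elbow-th ranked feature
    plus 0-4 standard deviations of the nonzero importances."""
    if elbow > len(table.ranked_features):
        raise ConfigurationError(
            f"elbow {elbow} exceeds number of ranked features "
            f"({len(table.ranked_features)})"
        )
    if elbow < 1:
        raise ConfigurationError("elbow must be >= 1")
    base = table.importance_of_rank(elbow)
    nonzero = np.array([v for v in table.importances.values() if v != 0.0])
    sd = float(np.std(nonzero)) if len(nonzero) else 0.0
    if sd == 0.0:
        import warnings

        warnings.warn("zero spread in aggregated importances; "
                      "all five thresholds coincide")
    thresholds = tuple(base + s * sd for s in range(5))
    return WarmStartPlan(elbow, base, sd, thresholds)  # type: ignore[arg-type]


def stage_pools(
    table: ImportanceTable, plan: WarmStartPlan
) -> list[list[str]]:
    """Feature pools for the five stages (a nested non-increasing chain)."""
    return [
        [f for f in table.ranked_features if table.importances[f] >= t]
        for t in plan.thresholds
    ]


def run_warm_start(
    evaluator,
    space: SearchSpace,
    table: ImportanceTable,
    plan: WarmStartPlan,
    config: GenerationConfig,
    rng: np.random.Generator,
    max_generations: int = 500,
    plateau_window: int = 20,
    plateau_tol: float = 1e-4,
    archive_size: int = 100,
) -> tuple[RunResult, list[RunResult]]:
    """Run the five constrained stages; return (winner, all stage results).

    Stages with an empty pool are skipped; every stage restarts evolution
    from a fresh random initial generation at half population.  The
    winner is the stage whose best archived model has the lowest fitness.
    """
    warm_config = config.for_phase(WARM_START)
    results: list[RunResult] = []
    for pool in stage_pools(table, plan):
        if not pool:
            continue
        stage_space = space.constrain_pool(pool)
        results.append(
            run_phase(
                evaluator,
                stage_space,
                warm_config,
                rng,
                max_generations=max_generations,
                plateau_window=plateau_window,
                plateau_tol=plateau_tol,
                archive_size=archive_size,
            )
        )
    if not results:
        raise ConfigurationError("all warm-start stages had empty pools")
    winner = min(results, key=lambda r: r.best.bic)
    return winner, results
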