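"""The evolutionary loop: rank, recombine, mutate, discard, replenish.

A generation step at base population ``n`` (standard phase):

* the 0.4n best models are paired by rank (1&2, 3&4, ...) and each pair
  averaged, hyperparameter by hyperparameter, into 0.2n recombined
  children that inherit the higher-ranked parent's feature set;
* the 0.2n best models are mutated into 0.2n children by shifting every
  hyperparameter by its fixed mutation step with independent random
  sign, clamped to range, keeping their own feature sets;
* the 0.4n worst models are discarded and 0.6n fresh random models are
  drawn, restoring the full complement of n models.

The warm-start phase halves the population (0.5n) with 0.2n recombined,
0.1n mutated and the remainder random.  The three best models of every
generation are retained in a convergence queue; the run terminates when
the best fitness plateaus (relative improvement over a sliding window
below tolerance) or at the generation cap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError
from .fitness import EvaluatedModel
from .search_space import Chromosome, SearchSpace, init_population, random_chromosome

__all__ = [
    "GenerationConfig",
    "RunResult",
    "rank",
    "recombine",
    "mutate",
    "generation_step",
    "update_queue",
    "has_plateaued",
    "run_phase",
    "run_standard_phase",
]

STANDARD = "standard"
WARM_START = "warm_start"


@dataclass(frozen=True)
class GenerationConfig:
    """Population fractions for one evolution phase.

    Standard phase at base n: 0.2n recombined (from 0.4n parents) +
    0.2n mutated + 0.6n random = n.  Warm-start phase: population 0.5n
    with 0.2n recombined + 0.1n mutated + the remainder random.
    """

    n: int = 100
    frac_recombine_parents: float = 0.4
    frac_mutate: float = 0.2
    frac_discard: float = 0.4
    frac_random: float = 0.6
    phase: str = STANDARD
    warm_population_frac: float = 0.5
    warm_recombine_children_frac: float = 0.2
    warm_mutate_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("population size must be >= 1")
        if self.phase not in (STANDARD, WARM_START):
            raise ConfigurationError(f"unknown phase {self.phase!r}")

    @property
    def population_size(self) -> int:
        if self.phase == WARM_START:
            return int(round(self.warm_population_frac * self.n))
        return self.n

    @property
    def n_recombined(self) -> int:
        if self.phase == WARM_START:
            return int(round(self.warm_recombine_children_frac * self.n))
        return int(round(self.frac_recombine_parents * self.n / 2))

    @property
    def n_mutated(self) -> int:
        if self.phase == WARM_START:
            return int(round(self.warm_mutate_frac * self.n))
        return int(round(self.frac_mutate * self.n))

    @property
    def n_random(self) -> int:
        return self.population_size - self.n_recombined - self.n_mutated

    @property
    def n_parents(self) -> int:
        return 2 * self.n_recombined

    def for_phase(self, phase: str) -> "GenerationConfig":
        return replace(self, phase=phase)


@dataclass
class RunResult:
    """Full record of one evolution phase."""

    queue: list[list[EvaluatedModel]]  # per generation, the 3 best
    best_history: list[float]  # per-generation best fitness
    archive: list[EvaluatedModel]  # best distinct models overall
    final_population: list[EvaluatedModel]
    n_generations: int
    converged: bool
    config: GenerationConfig
    seed: int | None = None
    # best value of each performance metric at each feature count, over
    # every model evaluated during the run (the elbow curve's envelope)
    envelope: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def best(self) -> EvaluatedModel:
        return self.archive[0]

    def to_dict(self) -> dict:
        return {
            "n_generations": self.n_generations,
            "converged": self.converged,
            "best_history": list(self.best_history),
            "seed": self.seed,
            "queue": [[m.to_dict() for m in gen] for gen in self.queue],
            "archive": [m.to_dict() for m in self.archive],
        }


def rank(population: list[EvaluatedModel]) -> list[EvaluatedModel]:
    """Stable sort by fitness ascending; ties by fewer features, then by
    insertion order.  Failed (+inf) fits always sort last."""
    indexed = list(enumerate(population))
    indexed.sort(key=lambda t: (t[1].bic, t[1].n_features, t[0]))
    return [m for _, m in indexed]


def recombine(
    ranked_parents: list[EvaluatedModel],
    space: SearchSpace,
    rng: np.random.Generator | None = None,
) -> list[Chromosome]:
    """Average consecutive-rank parent pairs into children.

    Parents (already ranked) are paired (1&2, 3&4, ...); each pair
    yields one child whose every hyperparameter is the arithmetic mean
    of its parents' values (integers rounded half-up, clamped).  The
    child inherits the higher-ranked parent's feature set.
    """
    if len(ranked_parents) % 2 != 0:
        raise ConfigurationError("parent count must be even")
    children = []
    for i in range(0, len(ranked_parents), 2):
        a = ranked_parents[i].chromosome
        b = ranked_parents[i + 1].chromosome
        values = {}
        for h in space.hyperparameters:
            mean = 0.5 * (
                a.hyperparameter_values[h.name] + b.hyperparameter_values[h.name]
            )
            values[h.name] = h.clamp(mean)
        children.append(Chromosome(values, a.features, provenance="recombined"))
    return children


def mutate(
    top_models: list[EvaluatedModel],
    space: SearchSpace,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """One child per model: every hyperparameter shifted by +/- its
    mutation step with independent random sign, clamped to range; the
    feature set is unchanged."""
    children = []
    for model in top_models:
        parent = model.chromosome
        values = {}
        for h in space.hyperparameters:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            values[h.name] = h.clamp(
                parent.hyperparameter_values[h.name] + sign * h.shift
            )
        children.append(Chromosome(values, parent.features, provenance="mutated"))
    return children


def generation_step(
    population: list[EvaluatedModel],
    space: SearchSpace,
    config: GenerationConfig,
    evaluator,
    rng: np.random.Generator,
) -> list[EvaluatedModel]:
    """One full generation: rank, breed, discard, replenish, evaluate."""
    expected = config.population_size
    if len(population) != expected:
        raise ConfigurationError(
            f"population size {len(population)} != expected {expected}"
        )
    ranked = rank(population)
    children = recombine(ranked[: config.n_parents], space, rng)
    children += mutate(ranked[: config.n_mutated], space, rng)
    children += [random_chromosome(space, rng) for _ in range(config.n_random)]
    return [evaluator(c, rng) for c in children]


def update_queue(
    queue: list[list[EvaluatedModel]], population: list[EvaluatedModel]
) -> list[list[EvaluatedModel]]:
    """Append the 3 best models of this generation to the queue."""
    best = rank(population)[:3]
    if len(population) < 3:
        warnings.warn("population smaller than 3; queue entry truncated")
    queue.append(best)
    return queue


def has_plateaued(best_history: list[float], window: int = 20, tol: float = 1e-4) -> bool:
    """True iff the best fitness in the last ``window`` generations
    improved by less than ``tol * |reference|`` over the best observed
    before that window (the first generation when none precede it)."""
    if window < 2:
        raise ConfigurationError("window must be >= 2")
    if len(best_history) < window:
        return False
    recent = min(best_history[-window:])
    prefix = best_history[:-window] or best_history[:1]
    reference = min(prefix)
    improvement = reference - recent
    scale = abs(reference)
    return improvement < (tol * scale if scale > 0 else tol)


def _archive_key(chromosome: Chromosome) -> tuple:
    def sig(v: float) -> float:
        if v == 0 or not math.isfinite(v):
            return v
        return round(v, 12 - 1 - int(math.floor(math.log10(abs(v)))))

    return (
        tuple(sorted(chromosome.features)),
        tuple((k, sig(chromosome.hyperparameter_values[k]))
              for k in sorted(chromosome.hyperparameter_values)),
    )


class _Archive:
    """Elitist archive of the best distinct models encountered."""

    def __init__(self, size: int = 100):
        self.size = size
        self._models: dict[tuple, EvaluatedModel] = {}

    def add(self, models: list[EvaluatedModel]) -> None:
        for m in models:
            if m.failed:
                continue
            key = _archive_key(m.chromosome)
            old = self._models.get(key)
            if old is None or m.bic < old.bic:
                self._models[key] = m
        if len(self._models) > self.size:
            kept = rank(list(self._models.values()))[: self.size]
            self._models = {_archive_key(m.chromosome): m for m in kept}

    def best_list(self) -> list[EvaluatedModel]:
        return rank(list(self._models.values()))[: self.size]


def run_phase(
    evaluator,
    space: SearchSpace,
    config: GenerationConfig,
    rng: np.random.Generator,
    max_generations: int = 500,
    plateau_window: int = 20,
    plateau_tol: float = 1e-4,
    archive_size: int = 100,
    seed: int | None = None,
) -> RunResult:
    """Run one evolution phase to plateau or the generation cap.

    A run that exhausts ``max_generations`` without plateauing is
    returned flagged unconverged, not raised.
    """
    population = [
        evaluator(c, rng)
        for c in init_population(space, config.population_size, rng)
    ]
    archive = _Archive(archive_size)
    queue: list[list[EvaluatedModel]] = []
    best_history: list[float] = []
    envelope: dict[str, dict[int, float]] = {}

    def record(pop):
        update_queue(queue, pop)
        archive.add(pop)
        best_history.append(queue[-1][0].bic)
        for m in pop:
            if m.failed:
                continue
            for metric, value in m.metrics.items():
                by_count = envelope.setdefault(metric, {})
                if m.n_features not in by_count or value > by_count[m.n_features]:
                    by_count[m.n_features] = value

    record(population)
    while len(best_history) < max_generations and not has_plateaued(
        best_history, plateau_window, plateau_tol
    ):
        population = generation_step(population, space, config, evaluator, rng)
        record(population)

    return RunResult(
        queue=queue,
        best_history=best_history,
        archive=archive.best_list(),
        final_population=population,
        n_generations=len(best_history),
        converged=has_plateaued(best_history, plateau_window, plateau_tol),
        config=config,
        seed=seed,
        envelope=envelope,
    )


def run_standard_phase(
    evaluator,
    space: SearchSpace,
    config: GenerationConfig,
    rng: np.random.Generator,
    **kwargs,
) -> RunResult:
    """The initial full-population phase (see :func:`run_phase`)."""
    return run_phase(evaluator, space, config.for_phase(STANDARD), rng, **kwargs)
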