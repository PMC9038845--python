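"""Joint hyperparameter / feature-subset search space.

A candidate solution ("chromosome") pairs a value for every tunable
hyperparameter of the inner learner with a subset of the feature pool.
Three built-in profiles cover the supported learners:

* ``net``    — Adam learning rate and the two exponential-decay rates
  (beta1, beta2) of a feedforward neural network;
* ``tree``   — maximum depth, node-partition threshold (gamma) and L1
  penalty (alpha) of a gradient-boosted tree ensemble;
* ``linear`` — L1 and L2 penalty weights of an elastic-net linear model.

Each profile carries the evolution range, the mutation shift (the fixed
step applied during mutation) and the library-default value used by the
no-optimization baseline.  Hyperparameters are drawn uniformly on their
range (uniform over integers for integer-valued ones); subset sizes are
drawn uniformly on ``[subset_min, min(subset_max, pool size)]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "HyperparameterSpec",
    "SearchSpace",
    "Chromosome",
    "random_chromosome",
    "init_population",
    "get_profile",
    "build_space",
    "PROFILES",
]


@dataclass(frozen=True)
class HyperparameterSpec:
    """Bounds, mutation step and baseline default for one hyperparameter.

    The ``default`` is the inner library's own setting and is allowed to
    sit outside the evolution range (the tree ensemble's L1 penalty
    defaults to 0 while its evolution range is 0.1-0.9); it is used only
    by the default-settings baseline, never sampled during evolution.
    """

    name: str
    low: float
    high: float
    shift: float
    integer_valued: bool = False
    default: float = 0.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigurationError(
                f"{self.name}: low ({self.low}) must be < high ({self.high})"
            )
        if not self.shift > 0:
            raise ConfigurationError(f"{self.name}: mutation shift must be > 0")
        if self.shift > self.high - self.low:
            raise ConfigurationError(
                f"{self.name}: shift {self.shift} exceeds range width"
            )

    def clamp(self, value: float) -> float:
        value = min(max(value, self.low), self.high)
        if self.integer_valued:
            # round half-up, then re-clamp (rounding can cross a bound)
            value = float(np.floor(value + 0.5))
            value = min(max(value, self.low), self.high)
        return value

    def sample(self, rng: np.random.Generator) -> float:
        if self.integer_valued:
            return float(rng.integers(int(self.low), int(self.high) + 1))
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class SearchSpace:
    """The joint space: hyperparameter specs plus the feature pool."""

    hyperparameters: tuple[HyperparameterSpec, ...]
    feature_pool: tuple[str, ...]
    subset_min: int = 1
    subset_max: int = 50

    def __post_init__(self) -> None:
        names = [h.name for h in self.hyperparameters]
        if len(set(names)) != len(names):
            raise ConfigurationError("hyperparameter names must be unique")
        if len(self.feature_pool) == 0:
            raise ConfigurationError("feature pool is empty")
        if len(set(self.feature_pool)) != len(self.feature_pool):
            raise ConfigurationError("feature names must be unique")
        if self.subset_min < 1:
            raise ConfigurationError("subset_min must be >= 1")
        if self.subset_min > self.subset_max:
            raise ConfigurationError("subset_min must be <= subset_max")

    @property
    def subset_cap(self) -> int:
        """Largest admissible subset size (subset_max clamped to the pool)."""
        return min(self.subset_max, len(self.feature_pool))

    def spec(self, name: str) -> HyperparameterSpec:
        for h in self.hyperparameters:
            if h.name == name:
                return h
        raise KeyError(name)

    def default_values(self) -> dict[str, float]:
        return {h.name: h.default for h in self.hyperparameters}

    def constrain_pool(self, features: list[str]) -> "SearchSpace":
        """A copy restricted to ``features``, subset bounds clamped."""
        pool = tuple(f for f in self.feature_pool if f in set(features))
        if not pool:
            raise ConfigurationError("constrained feature pool is empty")
        return replace(
            self,
            feature_pool=pool,
            subset_min=min(self.subset_min, len(pool)),
            subset_max=min(self.subset_max, len(pool)),
        )

    def validate(self, chromosome: "Chromosome") -> None:
        pool = set(self.feature_pool)
        if not (1 <= len(chromosome.features) <= self.subset_cap):
            raise ConfigurationError(
                f"feature subset size {len(chromosome.features)} outside "
                f"[1, {self.subset_cap}]"
            )
        if not set(chromosome.features) <= pool:
            raise ConfigurationError("chromosome features not in pool")
        for h in self.hyperparameters:
            v = chromosome.hyperparameter_values[h.name]
            if not (h.low <= v <= h.high):
                raise ConfigurationError(f"{h.name}={v} outside [{h.low}, {h.high}]")


@dataclass(frozen=True)
class Chromosome:
    """One candidate: hyperparameter values plus a selected-feature set."""

    hyperparameter_values: dict[str, float]
    features: frozenset[str]
    provenance: str = "random"  # random | recombined | mutated

    def to_dict(self) -> dict:
        return {
            "hyperparameters": {
                k: self.hyperparameter_values[k]
                for k in sorted(self.hyperparameter_values)
            },
            "features": sorted(self.features),
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def random_chromosome(space: SearchSpace, rng: np.random.Generator) -> Chromosome:
    """Draw one chromosome uniformly from the space.

    Hyperparameters are sampled uniformly on their ranges; the subset size
    uniformly on ``[subset_min, subset_cap]``; features without
    replacement from the pool.
    """
    values = {h.name: h.sample(rng) for h in space.hyperparameters}
    size = int(rng.integers(space.subset_min, space.subset_cap + 1))
    idx = rng.choice(len(space.feature_pool), size=size, replace=False)
    features = frozenset(space.feature_pool[i] for i in idx)
    return Chromosome(values, features, provenance="random")


def init_population(
    space: SearchSpace, n: int, rng: np.random.Generator
) -> list[Chromosome]:
    """Independently draw ``n`` random chromosomes (duplicates permitted)."""
    if n < 1:
        raise ConfigurationError(f"population size must be >= 1, got {n}")
    return [random_chromosome(space, rng) for _ in range(n)]


# Built-in profiles: (range low, high, mutation shift, integer flag, default).
PROFILES: dict[str, tuple[HyperparameterSpec, ...]] = {
    "net": (
        HyperparameterSpec("learning_rate", 0.00001, 0.01, 0.0001, False, 0.001),
        HyperparameterSpec("beta1", 0.9, 0.999, 0.001, False, 0.9),
        HyperparameterSpec("beta2", 0.9, 0.999, 0.001, False, 0.999),
    ),
    "tree": (
        HyperparameterSpec("max_depth", 2, 10, 1, True, 6),
        HyperparameterSpec("gamma", 0.0, 0.00001, 0.0000001, False, 0.0),
        HyperparameterSpec("alpha", 0.1, 0.9, 0.001, False, 0.0),
    ),
    "linear": (
        HyperparameterSpec("l1_penalty", 0.0, 1.0, 0.01, False, 0.15),
        HyperparameterSpec("l2_penalty", 0.0, 1.0, 0.01, False, 0.15),
    ),
}


def get_profile(kind: str) -> tuple[HyperparameterSpec, ...]:
    try:
        return PROFILES[kind]
    except KeyError:
        raise ConfigurationError(
            f"unknown inner-model kind {kind!r}; expected one of {sorted(PROFILES)}"
        ) from None


def build_space(
    kind: str,
    feature_pool: list[str] | tuple[str, ...],
    subset_min: int = 1,
    subset_max: int = 50,
) -> SearchSpace:
    """Search space for one of the built-in inner-model profiles."""
    return SearchSpace(
        hyperparameters=get_profile(kind),
        feature_pool=tuple(feature_pool),
        subset_min=subset_min,
        subset_max=subset_max,
    )


def space_from_dict(cfg: dict) -> SearchSpace:
    """Build a space from a configuration mapping.

    Expected keys: ``hyperparameters`` (list of mappings with name/low/
    high/shift and optional integer/default) plus ``feature_pool`` and
    optional ``subset_min``/``subset_max``.
    """
    specs = tuple(
        HyperparameterSpec(
            name=h["name"],
            low=float(h["low"]),
            high=float(h["high"]),
            shift=float(h["shift"]),
            integer_valued=bool(h.get("integer", False)),
            default=float(h.get("default", h["low"])),
        )
        for h in cfg["hyperparameters"]
    )
    return SearchSpace(
        hyperparameters=specs,
        feature_pool=tuple(cfg["feature_pool"]),
        subset_min=int(cfg.get("subset_min", 1)),
        subset_max=int(cfg.get("subset_max", 50)),
    )
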