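"""Genetic-algorithm search over fixed-dimension feature subsets.

The search space is all k-element subsets of the feature pool (k fixed in
2–5: the vector dimension is a study constraint, not a search variable).
A chromosome is a sorted tuple of feature indices; its fitness is the
cross-validated classification error (1 − accuracy/100) of the quadratic
discriminant on that subset. The generational loop is

1. initialize a population of random distinct subsets;
2. evaluate fitness (cached by subset within a run);
3. tournament-select parents;
4. breed by uniform subset crossover with repair (dedupe, refill);
5. mutate by swapping one index for an unused one;
6. replace all but the elite with the offspring.

Elitism makes the per-generation best fitness monotone non-increasing.
An exhaustive-enumeration oracle over the same fitness function verifies
the GA on small pools.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from . import classify
from .features import FeatureMatrix

EXHAUSTIVE_BUDGET = 20_000


@dataclass(frozen=True)
class Chromosome:
    """Feature-index subset of fixed dimension with its fitness (CV error)."""

    indices: tuple[int, ...]
    fitness: float

    def feature_names(self, pool: list[str]) -> list[str]:
        return [pool[i] for i in self.indices]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 40
    generations: int = 60
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    elitism_count: int = 2
    tournament_size: int = 3
    seed: int = 0
    k: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.crossover_rate <= 1 or not 0 <= self.mutation_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.k not in (2, 3, 4, 5):
            raise ValueError("subset dimension k must be in {2, 3, 4, 5}")
        if not 0 <= self.elitism_count <= self.population_size:
            raise ValueError("elitism_count must be within the population size")


class _FitnessCache:
    """Cross-validated error per subset, evaluated once per run."""

    def __init__(
        self, features: FeatureMatrix, pool: list[str], cv_seed: int, n_splits: int
    ):
        self.features = features
        self.pool = pool
        self.cv_seed = cv_seed
        self.n_splits = n_splits
        self._cache: dict[tuple[int, ...], float] = {}

    def __call__(self, indices: tuple[int, ...]) -> float:
        key = tuple(sorted(indices))
        if key not in self._cache:
            subset = [self.pool[i] for i in key]
            report = classify.cross_validated_report(
                self.features, subset, n_splits=self.n_splits, seed=self.cv_seed
            )
            self._cache[key] = 1.0 - report.accuracy / 100.0
        return self._cache[key]

    @property
    def evaluations(self) -> dict[tuple[int, ...], float]:
        return dict(self._cache)


def _sorted_key(indices) -> tuple[int, ...]:
    return tuple(sorted(int(i) for i in indices))


def _best(cands: dict[tuple[int, ...], float]) -> tuple[tuple[int, ...], float]:
    """Minimum-fitness subset; ties broken lexicographically on indices."""
    return min(cands.items(), key=lambda kv: (kv[1], kv[0]))


@dataclass
class GAResult:
    best: Chromosome
    history: list[float]
    evaluations: dict[tuple[int, ...], float] = field(repr=False, default_factory=dict)


def run_ga(
    features: FeatureMatrix,
    cfg: GAConfig,
    pool: list[str] | None = None,
    cv_splits: int = 5,
) -> GAResult:
    """Run the generational GA; deterministic under ``cfg.seed``."""
    pool = list(pool) if pool is not None else features.feature_names
    n_pool = len(pool)
    if n_pool < cfg.k:
        raise ValueError(f"feature pool of {n_pool} smaller than k={cfg.k}")
    rng = np.random.default_rng(cfg.seed)
    fitness = _FitnessCache(features, pool, cv_seed=cfg.seed, n_splits=cv_splits)

    def random_subset() -> tuple[int, ...]:
        return _sorted_key(rng.choice(n_pool, size=cfg.k, replace=False))

    def tournament(pop: list[tuple[int, ...]]) -> tuple[int, ...]:
        picks = rng.integers(0, len(pop), size=cfg.tournament_size)
        return min((pop[i] for i in picks), key=lambda s: (fitness(s), s))

    def crossover(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
        union = sorted(set(a) | set(b))
        child = list(rng.choice(union, size=min(cfg.k, len(union)), replace=False))
        while len(child) < cfg.k:  # refill if union was too small
            cand = int(rng.integers(0, n_pool))
            if cand not in child:
                child.append(cand)
        return _sorted_key(child)

    def mutate(s: tuple[int, ...]) -> tuple[int, ...]:
        out = list(s)
        for pos in range(cfg.k):
            if rng.random() < cfg.mutation_rate:
                unused = [i for i in range(n_pool) if i not in out]
                if unused:
                    out[pos] = unused[int(rng.integers(0, len(unused)))]
        return _sorted_key(out)

    population = [random_subset() for _ in range(cfg.population_size)]
    history: list[float] = []
    for _ in range(cfg.generations):
        ranked = sorted(population, key=lambda s: (fitness(s), s))
        history.append(fitness(ranked[0]))
        elite = ranked[: cfg.elitism_count]
        offspring = list(elite)
        while len(offspring) < cfg.population_size:
            parent_a = tournament(population)
            if rng.random() < cfg.crossover_rate:
                parent_b = tournament(population)
                child = crossover(parent_a, parent_b)
            else:
                child = parent_a
            offspring.append(mutate(child))
        population = offspring

    key, fit_val = _best(fitness.evaluations)
    return GAResult(
        best=Chromosome(indices=key, fitness=fit_val),
        history=history,
        evaluations=fitness.evaluations,
    )


def exhaustive_best(
    features: FeatureMatrix,
    k: int,
    pool: list[str] | None = None,
    cv_seed: int = 0,
    cv_splits: int = 5,
) -> Chromosome:
    """Evaluate every k-subset; the oracle against which the GA is checked.

    Uses the identical cross-validated fitness; ties broken
    lexicographically on sorted indices. Refuses pools with more than
    ``EXHAUSTIVE_BUDGET`` combinations.
    """
    pool = list(pool) if pool is not None else features.feature_names
    n_combi = math.comb(len(pool), k)
    if n_combi > EXHAUSTIVE_BUDGET:
        raise ValueError(
            f"C({len(pool)}, {k}) = {n_combi} exceeds the exhaustive "
            f"budget of {EXHAUSTIVE_BUDGET}"
        )
    fitness = _FitnessCache(features, pool, cv_seed=cv_seed, n_splits=cv_splits)
    for combo in itertools.combinations(range(len(pool)), k):
        fitness(combo)
    key, fit_val = _best(fitness.evaluations)
    return Chromosome(indices=key, fitness=fit_val)


def rank_vectors(
    features: FeatureMatrix,
    ks: list[int],
    top_n: int = 5,
    pool: list[str] | None = None,
    ga_cfg: GAConfig | None = None,
    cv_splits: int = 5,
) -> dict[int, list[dict]]:
    """Top feature subsets per dimension, ranked by CV accuracy.

    For each k the GA is run and every subset it evaluated is ranked; the
    ``top_n`` best (accuracy descending, lexicographic index tie-break)
    are reported with their per-class sensitivity and specificity.
    """
    pool = list(pool) if pool is not None else features.feature_names
    base = ga_cfg or GAConfig()
    out: dict[int, list[dict]] = {}
    for k in ks:
        if k not in (2, 3, 4, 5):
            raise ValueError("vector dimensions must be in {2, 3, 4, 5}")
        cfg = GAConfig(
            population_size=base.population_size,
            generations=base.generations,
            crossover_rate=base.crossover_rate,
            mutation_rate=base.mutation_rate,
            elitism_count=base.elitism_count,
            tournament_size=base.tournament_size,
            seed=base.seed + k,
            k=k,
        )
        result = run_ga(features, cfg, pool=pool, cv_splits=cv_splits)
        ranked = sorted(result.evaluations.items(), key=lambda kv: (kv[1], kv[0]))
        rows = []
        for indices, err in ranked[:top_n]:
            names = [pool[i] for i in indices]
            report = classify.cross_validated_report(
                features, names, n_splits=cv_splits, seed=cfg.seed
            )
            rows.append(
                {
                    "features": names,
                    "accuracy": report.accuracy,
                    "sensitivity": report.sensitivity,
                    "specificity": report.specificity,
                }
            )
        out[k] = rows
    return out
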