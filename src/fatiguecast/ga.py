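"""Genetic-algorithm wrapper feature selection.

Searches for the fixed-length feature subset (the *chromosome*, a set of L
distinct feature indices) that minimizes the training-fold mean squared
error of the least-squares linear discriminant — a wrapper selector, where
the classifier itself scores candidate subsets.

One generation = evaluate fitness -> rank-select the top parent fraction
-> refill the population with random-crossover offspring of parent pairs
-> mutate a fixed fraction of offspring gene slots. The best individuals
(elitism, default 1) are carried over unchanged, which makes best-so-far
fitness monotonically non-increasing across generations. The search
terminates after a fixed number of generations and returns the best
chromosome ever evaluated.

Defaults: chromosome length 8, population 10xL, parent fraction 10%,
mutation rate 1% of gene slots, 100 generations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import lsld_training_mse

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Chromosome:
    """A candidate feature subset: L distinct feature indices.

    Semantically a set — fitness is invariant to gene order — stored as an
    ordered tuple for reproducibility.
    """

    genes: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes",
                           tuple(int(g) for g in self.genes))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("chromosome genes must be distinct")
        if any(g < 0 for g in self.genes):
            raise ValueError("negative feature index")

    def __len__(self) -> int:
        return len(self.genes)

    def key(self) -> tuple[int, ...]:
        """Order-free identity (sorted genes), used for fitness caching."""
        return tuple(sorted(self.genes))


@dataclass
class GaConfig:
    """GA settings; ``population_size`` defaults to 10 x chromosome_length."""

    chromosome_length: int = 8
    population_size: int | None = None
    parent_fraction: float = 0.10
    mutation_rate: float = 0.01
    generations: int = 100
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size is None:
            self.population_size = 10 * self.chromosome_length
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 < self.parent_fraction <= 1:
            raise ValueError("parent_fraction must be in (0, 1]")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.chromosome_length < 1 or self.generations < 0:
            raise ValueError("invalid chromosome_length or generations")
        if not 0 <= self.elitism <= self.population_size:
            raise ValueError("elitism out of range")


@dataclass
class GaHistory:
    """Per-generation best fitness / chromosome (entry 0 is the initial
    population) and the best-ever solution."""

    best_fitness: list[float] = field(default_factory=list)
    best_chromosome: list[Chromosome] = field(default_factory=list)
    n_evaluations: int = 0

    @property
    def final_best(self) -> Chromosome:
        return self.best_chromosome[int(np.argmin(self.best_fitness))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "generation": range(len(self.best_fitness)),
            "best_mse": self.best_fitness,
            "best_genes": [" ".join(map(str, c.genes))
                           for c in self.best_chromosome],
        })


def init_population(
    D: int, config: GaConfig, rng: np.random.Generator | None = None
) -> list[Chromosome]:
    """Uniform random L-subsets of [0, D), ``population_size`` of them."""
    L = config.chromosome_length
    if L > D:
        raise ValueError(f"chromosome length {L} exceeds feature count {D}")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    return [Chromosome(tuple(rng.choice(D, size=L, replace=False)))
            for _ in range(config.population_size)]


def fitness(chromosome: Chromosome, X_train: np.ndarray,
            y_train: np.ndarray) -> float:
    """Training MSE of the LSLD restricted to the chromosome's features
    (lower is fitter)."""
    X_train = np.asarray(X_train, dtype=float)
    if max(chromosome.genes) >= X_train.shape[1]:
        raise ValueError("chromosome gene outside the feature matrix")
    cols = sorted(chromosome.genes)  # order-free by construction
    return lsld_training_mse(X_train[:, cols], np.asarray(y_train, float))


def select_parents(
    population: list[Chromosome],
    fitnesses: np.ndarray,
    config: GaConfig,
) -> list[Chromosome]:
    """Rank selection: the ceil(parent_fraction x population) individuals
    with lowest MSE; ties keep stable population order."""
    if len(population) == 0:
        raise ValueError("empty population")
    n_parents = math.ceil(config.parent_fraction * len(population))
    order = np.argsort(np.asarray(fitnesses), kind="stable")
    return [population[i] for i in order[:n_parents]]


def crossover(
    parent_a: Chromosome,
    parent_b: Chromosome,
    rng: np.random.Generator,
    n_features: int,
) -> Chromosome:
    """Uniform random crossover: each gene position is drawn from either
    parent with equal probability; duplicate genes are repaired by
    resampling from the parents' gene union, then (if exhausted) from the
    remaining feature pool."""
    if len(parent_a) != len(parent_b):
        raise ValueError("parents must have equal chromosome length")
    L = len(parent_a)
    pick_a = rng.integers(0, 2, size=L).astype(bool)
    raw = [parent_a.genes[i] if pick_a[i] else parent_b.genes[i]
           for i in range(L)]
    child: list[int] = []
    seen: set[int] = set()
    n_dups = 0
    for g in raw:
        if g in seen:
            n_dups += 1
        else:
            child.append(g)
            seen.add(g)
    if n_dups:
        union = sorted((set(parent_a.genes) | set(parent_b.genes)) - seen)
        for _ in range(n_dups):
            if union:
                g = union.pop(int(rng.integers(0, len(union))))
            else:
                pool = np.setdiff1d(np.arange(n_features),
                                    np.fromiter(seen, dtype=int))
                g = int(pool[rng.integers(0, len(pool))])
            child.append(g)
            seen.add(g)
    return Chromosome(tuple(child))


def mutate(
    population: list[Chromosome],
    D: int,
    config: GaConfig,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """Mutate exactly round(mutation_rate x total gene slots) slots, chosen
    uniformly without replacement across the given population; each mutated
    slot receives a uniform random feature not already in its chromosome.

    ``run_ga`` passes only the offspring here, so elites are never mutated.
    """
    if not population:
        return []
    L = len(population[0])
    total = len(population) * L
    n_mut = int(math.floor(config.mutation_rate * total + 0.5))
    if config.mutation_rate > 0:
        # small populations would otherwise round to zero mutations and
        # freeze the gene pool
        n_mut = max(1, n_mut)
    if n_mut == 0:
        return list(population)
    genes = [list(c.genes) for c in population]
    slots = rng.choice(total, size=n_mut, replace=False)
    saturated_logged = False
    for slot in sorted(slots):
        i, j = divmod(int(slot), L)
        current = set(genes[i])
        pool = np.setdiff1d(np.arange(D), np.fromiter(current, dtype=int))
        if len(pool) == 0:
            if not saturated_logged:
                logger.warning("chromosome saturates the feature space; "
                               "mutation has no replacement candidates")
                saturated_logged = True
            continue
        genes[i][j] = int(pool[rng.integers(0, len(pool))])
    return [Chromosome(tuple(g)) for g in genes]


def run_ga(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: GaConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Chromosome, GaHistory]:
    """Run the full GA on one training fold; returns the best-ever
    chromosome and the per-generation history.

    Fitness is cached by gene set, so re-evaluating elites or revisited
    subsets costs nothing.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if np.unique(y_train).size < 2:
        raise ValueError("training labels contain a single class")
    D = X_train.shape[1]
    rng = np.random.default_rng(config.seed) if rng is None else rng

    cache: dict[tuple[int, ...], float] = {}
    history = GaHistory()

    def evaluate(pop: list[Chromosome]) -> np.ndarray:
        fits = np.empty(len(pop))
        for i, c in enumerate(pop):
            key = c.key()
            if key not in cache:
                cache[key] = fitness(c, X_train, y_train)
                history.n_evaluations += 1
            fits[i] = cache[key]
        return fits

    population = init_population(D, config, rng)
    fits = evaluate(population)

    best_i = int(np.argmin(fits))
    best_chrom, best_fit = population[best_i], float(fits[best_i])
    history.best_fitness.append(best_fit)
    history.best_chromosome.append(best_chrom)

    for _ in range(config.generations):
        order = np.argsort(fits, kind="stable")
        elites = [population[i] for i in order[: config.elitism]]
        parents = select_parents(population, fits, config)
        offspring = []
        for _ in range(config.population_size - config.elitism):
            ia, ib = rng.integers(0, len(parents), size=2)
            offspring.append(crossover(parents[ia], parents[ib], rng, D))
        offspring = mutate(offspring, D, config, rng)
        population = elites + offspring
        fits = evaluate(population)
        gen_i = int(np.argmin(fits))
        # history records the current population's best; with elitism >= 1
        # this is also the best-so-far and is non-increasing
        history.best_fitness.append(float(fits[gen_i]))
        history.best_chromosome.append(population[gen_i])
        if fits[gen_i] < best_fit:
            best_chrom, best_fit = population[gen_i], float(fits[gen_i])

    return best_chrom, history
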