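"""Genetic-algorithm selector: operators, invariants and the exhaustive
small-instance oracle."""

import itertools

import numpy as np
import pytest

from fatiguecast import Chromosome, GaConfig, run_ga
from fatiguecast.ga import (
    crossover,
    fitness,
    init_population,
    mutate,
    select_parents,
)


def make_training_data(seed=0, n=30, d=10, informative=(2, 7), effect=3.0):
    """Labels driven by a planted feature pair; everything else is noise."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = np.array([-1] * (n // 2) + [1] * (n - n // 2), dtype=float)
    for j in informative:
        X[:, j] += effect / 2 * y
    return X, y


def exhaustive_best_mse(X, y, L):
    """Brute-force oracle: minimum LSLD training MSE over all C(D, L)
    subsets."""
    return min(fitness(Chromosome(c), X, y)
               for c in itertools.combinations(range(X.shape[1]), L))


class TestChromosome:
    def test_invariants(self):
        with pytest.raises(ValueError, match="distinct"):
            Chromosome((1, 1, 2))
        with pytest.raises(ValueError, match="negative"):
            Chromosome((-1, 2))
        assert Chromosome((3, 1)).key() == Chromosome((1, 3)).key()


class TestInitPopulation:
    def test_default_population_is_ten_times_length(self):
        pop = init_population(596, GaConfig(chromosome_length=8, seed=0))
        assert len(pop) == 80
        for c in pop:
            assert len(c) == 8
            assert len(set(c.genes)) == 8
            assert max(c.genes) < 596

    def test_length_equals_dimension_forces_full_set(self):
        pop = init_population(5, GaConfig(chromosome_length=5, seed=0))
        assert all(c.key() == (0, 1, 2, 3, 4) for c in pop)

    def test_seed_determinism(self):
        cfg = GaConfig(chromosome_length=4, seed=9)
        assert [c.genes for c in init_population(20, cfg)] == \
            [c.genes for c in init_population(20, GaConfig(
                chromosome_length=4, seed=9))]

    def test_length_exceeding_dimension_rejected(self):
        with pytest.raises(ValueError):
            init_population(3, GaConfig(chromosome_length=4))


class TestFitness:
    def test_perfect_feature_gives_zero_mse(self):
        X = np.array([[-1.0, 5.0], [1.0, 5.0]])
        assert fitness(Chromosome((0,)), X, [-1, 1]) < 1e-20

    def test_constant_features_give_unit_mse_on_balanced_labels(self):
        X = np.ones((4, 2))
        y = [-1, -1, 1, 1]
        assert fitness(Chromosome((0, 1)), X, y) == pytest.approx(1.0)

    def test_gene_order_invariance(self, rng):
        X = rng.standard_normal((12, 6))
        y = np.array([-1] * 6 + [1] * 6)
        assert fitness(Chromosome((4, 0, 2)), X, y) == \
            pytest.approx(fitness(Chromosome((2, 4, 0)), X, y))


class TestSelectParents:
    def test_ten_percent_of_eighty_is_eight(self):
        pop = [Chromosome((i,)) for i in range(80)]
        fits = np.arange(80.0)
        parents = select_parents(pop, fits, GaConfig(chromosome_length=1,
                                                     population_size=80))
        assert len(parents) == 8
        assert [p.genes[0] for p in parents] == list(range(8))

    def test_ties_keep_stable_order(self):
        pop = [Chromosome((i,)) for i in range(10)]
        parents = select_parents(pop, np.zeros(10),
                                 GaConfig(chromosome_length=1,
                                          population_size=10,
                                          parent_fraction=0.3))
        assert [p.genes[0] for p in parents] == [0, 1, 2]

    def test_fraction_one_keeps_everyone(self):
        pop = [Chromosome((i,)) for i in range(5)]
        parents = select_parents(pop, np.arange(5.0),
                                 GaConfig(chromosome_length=1,
                                          population_size=5,
                                          parent_fraction=1.0))
        assert len(parents) == 5

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_parents([], np.array([]), GaConfig())


class TestCrossover:
    def test_identical_parents_reproduce_exactly(self, rng):
        p = Chromosome((3, 1, 4))
        child = crossover(p, p, rng, n_features=10)
        assert child.key() == p.key()

    def test_disjoint_parents_child_within_union(self, rng):
        a, b = Chromosome(tuple(range(8))), Chromosome(tuple(range(8, 16)))
        for _ in range(50):
            child = crossover(a, b, rng, n_features=16)
            assert set(child.genes) <= set(range(16))
            assert len(set(child.genes)) == 8

    def test_union_coverage_over_many_seeds(self):
        """Every gene of both parents appears in some child (Monte-Carlo)."""
        a, b = Chromosome((0, 1, 2, 3)), Chromosome((4, 5, 6, 7))
        seen = set()
        rng = np.random.default_rng(0)
        for _ in range(300):
            seen |= set(crossover(a, b, rng, n_features=8).genes)
        assert seen == set(range(8))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            crossover(Chromosome((0, 1)), Chromosome((0, 1, 2)), rng, 5)


class TestMutate:
    def test_rate_zero_is_identity(self, rng):
        pop = init_population(20, GaConfig(chromosome_length=4, seed=0))
        out = mutate(pop, 20, GaConfig(chromosome_length=4,
                                       mutation_rate=0.0), rng)
        assert [c.genes for c in out] == [c.genes for c in pop]

    def test_saturated_chromosomes_unchanged_and_logged(self, rng, caplog):
        pop = [Chromosome((0, 1, 2))] * 4
        with caplog.at_level("WARNING"):
            out = mutate(pop, 3, GaConfig(chromosome_length=3,
                                          population_size=4,
                                          mutation_rate=1.0), rng)
        assert all(c.key() == (0, 1, 2) for c in out)
        assert "saturat" in caplog.text

    def test_exact_slot_count_at_one_percent(self, rng):
        """80 chromosomes x 8 genes at 1% -> exactly round(640 x 0.01) = 6
        mutated gene slots."""
        cfg = GaConfig(chromosome_length=8, seed=1, mutation_rate=0.01)
        pop = init_population(600, cfg, rng)
        out = mutate(pop, 600, cfg, rng)
        changed = sum(
            len(set(a.genes) ^ set(b.genes)) // 2
            for a, b in zip(pop, out)
        )
        assert changed == 6  # distinct replacements cannot collide here
        for c in out:
            assert len(set(c.genes)) == 8

    def test_invariants_preserved_under_heavy_mutation(self, rng):
        cfg = GaConfig(chromosome_length=5, population_size=30,
                       mutation_rate=0.5)
        pop = init_population(12, cfg, rng)
        out = mutate(pop, 12, cfg, rng)
        for c in out:
            assert len(set(c.genes)) == 5
            assert max(c.genes) < 12


class TestRunGa:
    CFG = GaConfig(chromosome_length=2, generations=100, seed=0)

    def test_finds_exhaustive_optimum_on_small_instance(self):
        X, y = make_training_data()
        best, history = run_ga(X, y, self.CFG)
        oracle = exhaustive_best_mse(X, y, 2)
        assert history.best_fitness[-1] == pytest.approx(oracle, abs=1e-10)
        assert set(best.genes) == {2, 7}

    def test_elitism_makes_best_fitness_monotone(self):
        X, y = make_training_data(seed=5)
        _, history = run_ga(X, y, GaConfig(chromosome_length=3,
                                           generations=40, seed=1))
        diffs = np.diff(history.best_fitness)
        assert (diffs <= 1e-12).all()

    def test_seed_determinism(self):
        X, y = make_training_data(seed=2)
        cfg = GaConfig(chromosome_length=2, generations=30, seed=0)
        b1, h1 = run_ga(X, y, cfg)
        b2, h2 = run_ga(X, y, GaConfig(chromosome_length=2,
                                       generations=30, seed=0))
        assert b1.genes == b2.genes
        assert h1.best_fitness == h2.best_fitness

    def test_length_equals_dimension_converges_immediately(self):
        X, y = make_training_data(d=3, informative=(0, 2))
        best, history = run_ga(X, y, GaConfig(chromosome_length=3,
                                              generations=5, seed=0))
        assert best.key() == (0, 1, 2)
        assert len(set(history.best_fitness)) == 1

    def test_permutation_equivariance_of_the_optimum(self):
        """On a unique-optimum instance, permuting feature columns maps the
        selected subset through the same permutation."""
        X, y = make_training_data()
        perm = np.random.default_rng(3).permutation(X.shape[1])
        best_perm, _ = run_ga(X[:, perm], y, self.CFG)
        mapped = {perm[g] for g in best_perm.genes}
        assert mapped == {2, 7}

    def test_single_class_rejected(self):
        X = np.zeros((4, 3))
        with pytest.raises(ValueError, match="single class"):
            run_ga(X, np.ones(4), self.CFG)

    def test_history_is_exportable(self):
        X, y = make_training_data()
        _, history = run_ga(X, y, GaConfig(chromosome_length=2,
                                           generations=5, seed=0))
        frame = history.to_frame()
        assert list(frame.columns) == ["generation", "best_mse",
                                       "best_genes"]
        assert len(frame) == 6  # initial population + 5 generations
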