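import numpy as np
import pandas as pd
import pytest

import ehgpredict as ep
from ehgpredict.ga import (GAConfig, FitnessEvaluator, NEG_INF,
                           evolve_generation, exhaustive_best_mask, mask_of,
                           run_ga)
from ehgpredict.pipeline import FeatureTable


@pytest.fixture(scope="module")
def planted_small():
    """8-feature table with 2 informative columns, balanced + partitioned."""
    t = ep.gen_feature_table(30, 2, 6, 2.0, seed=3)
    bal, parts = ep.balance_and_partition(t, seed=2)
    return bal, parts


class TestFitness:
    def test_parsimony_arithmetic(self, planted_small, monkeypatch):
        bal, parts = planted_small
        ev = FitnessEvaluator(bal, parts)
        # force mean validation F1 = 0.8 and check the parsimony weighting
        monkeypatch.setattr(ev, "mean_validation_f1", lambda mask: 0.8)
        ev.n_feat = 30
        mask = np.zeros(30, dtype=bool)
        mask[:10] = True
        assert ev(mask) == pytest.approx(16.0)

    def test_full_mask_scores_zero(self, planted_small):
        bal, parts = planted_small
        ev = FitnessEvaluator(bal, parts)
        assert ev(np.ones(bal.X.shape[1], dtype=bool)) == 0.0

    def test_empty_mask_never_selected(self, planted_small):
        bal, parts = planted_small
        ev = FitnessEvaluator(bal, parts)
        assert ev(np.zeros(bal.X.shape[1], dtype=bool)) == NEG_INF

    def test_smaller_mask_wins_at_equal_f1(self, planted_small, monkeypatch):
        bal, parts = planted_small
        ev = FitnessEvaluator(bal, parts)
        monkeypatch.setattr(ev, "mean_validation_f1", lambda mask: 0.75)
        small = np.zeros(8, dtype=bool)
        small[:2] = True
        large = np.zeros(8, dtype=bool)
        large[:5] = True
        assert ev(small) > ev(large)

    def test_deterministic_recomputation(self, planted_small):
        bal, parts = planted_small
        mask = np.array([1, 0, 1, 0, 0, 0, 1, 0], dtype=bool)
        a = ep.fitness(mask, bal, parts)
        b = ep.fitness(mask, bal, parts)
        assert a == b


class TestEvolveGeneration:
    def test_no_operators_copies_tournament_winners(self, rng):
        cfg = GAConfig(genome_length=6, crossover_prob=0.0, mutation_prob=0.0)
        pop = rng.uniform(size=(6, 6))
        fit = rng.uniform(size=6)
        new = evolve_generation(pop, fit, cfg, rng)
        pop_rows = {tuple(np.round(r, 12)) for r in pop}
        assert all(tuple(np.round(r, 12)) in pop_rows for r in new)

    def test_elites_preserved(self, rng):
        cfg = GAConfig(genome_length=5)
        pop = rng.uniform(size=(5, 5))
        fit = np.array([0.1, 0.9, 0.5, 0.3, 0.7])
        new = evolve_generation(pop, fit, cfg, rng)
        np.testing.assert_array_equal(new[0], pop[1])
        np.testing.assert_array_equal(new[1], pop[4])

    def test_arithmetic_crossover_convexity(self, rng):
        cfg = GAConfig(genome_length=10, crossover_prob=1.0,
                       mutation_prob=0.0, elite_count=0)
        for _ in range(100):  # ~1000 crossovers total across children
            pop = rng.uniform(size=(10, 10))
            fit = rng.uniform(size=10)
            new = evolve_generation(pop, fit, cfg, rng)
            lo, hi = pop.min(axis=0), pop.max(axis=0)
            assert np.all(new >= lo - 1e-12) and np.all(new <= hi + 1e-12)


class TestRunGA:
    def test_two_feature_problem_selects_the_informative_one(self):
        t = ep.gen_feature_table(30, 1, 1, 3.0, seed=17)
        bal, parts = ep.balance_and_partition(t, seed=5)
        # population = genome length is degenerate at N=2 (all elites);
        # give the search a small working population instead
        cfg = GAConfig(genome_length=2, population_size=6, seed=1,
                       stall_generations=20, max_generations=100)
        res = run_ga(bal, parts, cfg)
        assert res.selected(bal.X.columns) == ["inf_1"]
        # exhaustive check over the 3 nonempty masks
        best_mask, best_fit = exhaustive_best_mask(bal, parts)
        assert res.best_fitness == pytest.approx(best_fit)
        np.testing.assert_array_equal(res.best_mask, best_mask)

    def test_history_best_nondecreasing(self, planted_small):
        bal, parts = planted_small
        cfg = GAConfig(genome_length=8, seed=2, stall_generations=20,
                       max_generations=60)
        res = run_ga(bal, parts, cfg)
        best = [h[0] for h in res.history]
        assert all(a <= b + 1e-12 for a, b in zip(best, best[1:]))

    def test_deterministic_given_seed(self, planted_small):
        bal, parts = planted_small
        cfg = GAConfig(genome_length=8, seed=11, stall_generations=15,
                       max_generations=40)
        a = run_ga(bal, parts, cfg)
        b = run_ga(bal, parts, cfg)
        np.testing.assert_array_equal(a.best_mask, b.best_mask)
        assert a.history == b.history

    def test_near_exhaustive_optimum_small_n(self, planted_small):
        bal, parts = planted_small
        _, best_fit = exhaustive_best_mask(bal, parts)
        for seed in (0, 1, 2):
            res = run_ga(bal, parts, GAConfig(genome_length=8, seed=seed))
            assert res.best_fitness >= 0.95 * best_fit

    def test_genome_length_mismatch_rejected(self, planted_small):
        bal, parts = planted_small
        with pytest.raises(ValueError):
            run_ga(bal, parts, GAConfig(genome_length=5))


def test_mask_threshold():
    genes = np.array([0.49, 0.5, 0.51, 0.0, 1.0])
    np.testing.assert_array_equal(mask_of(genes),
                                  [False, True, True, False, True])
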