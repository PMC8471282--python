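"""Genetic-algorithm wrapper feature selection.

Chromosomes are real gene vectors in [0, 1] thresholded at 0.5 into a
binary feature mask (arithmetic crossover is defined on real genes;
thresholding reconciles it with binary masking).  The fitness of a mask
is the parsimony-weighted mean validation F1 over the shared holdout
partitions:

    fitness = mean_validation_F1 * (NFeat - NCFeat)

where NFeat is the size of the initial feature set and NCFeat the size
of the current subset — so the all-features mask scores 0 regardless of
its F1, and among masks with equal F1 the smaller wins.  Population
size and genome length both equal NFeat; selection is tournament-of-2
with 2 elites, arithmetic crossover with probability 0.8, uniform
per-gene mutation with probability 0.01, and the run stops when the
best fitness has not improved by more than 1e-6 for 150 consecutive
generations (or at a safety cap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .pipeline import FeatureTable, PartitionSet, classification_metrics, lda_fit

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")


@dataclass
class GAConfig:
    genome_length: int
    population_size: int | None = None  # defaults to genome_length
    tournament_size: int = 2
    elite_count: int = 2
    crossover_prob: float = 0.8
    mutation_prob: float = 0.01
    stall_generations: int = 150
    fitness_tolerance: float = 1e-6
    max_generations: int = 2000
    seed: int = 0
    binary_crossover: bool = False  # uniform crossover on binary genes

    def __post_init__(self) -> None:
        if self.population_size is None:
            self.population_size = self.genome_length
        for p in (self.crossover_prob, self.mutation_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GARunResult:
    best_mask: np.ndarray
    best_fitness: float
    history: list = field(default_factory=list)  # (best, mean) per generation
    generations_run: int = 0

    def selected(self, feature_names) -> list:
        return [n for n, b in zip(feature_names, self.best_mask) if b]


def mask_of(genes: np.ndarray) -> np.ndarray:
    return genes >= 0.5


class FitnessEvaluator:
    """Parsimony-weighted validation F1, cached per mask."""

    def __init__(self, table: FeatureTable, partitions: PartitionSet):
        self.X = table.X.to_numpy(dtype=float)
        self.y = table.labels.to_numpy()
        self.partitions = partitions.partitions
        self.n_feat = self.X.shape[1]
        self._cache: dict = {}

    def mean_validation_f1(self, mask: np.ndarray) -> float:
        f1s = []
        for tr, va, _ in self.partitions:
            model = lda_fit(self.X[np.ix_(tr, np.flatnonzero(mask))],
                            self.y[tr])
            Xva = self.X[np.ix_(va, np.flatnonzero(mask))]
            m = classification_metrics(self.y[va], model.predict(Xva))
            f1s.append(0.0 if np.isnan(m["F1"]) else m["F1"] / 100.0)
        return float(np.mean(f1s))

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        n_sel = int(mask.sum())
        if n_sel == 0:
            return NEG_INF
        key = mask.tobytes()
        if key not in self._cache:
            f1 = self.mean_validation_f1(mask)
            self._cache[key] = f1 * (self.n_feat - n_sel)
        return self._cache[key]


def fitness(mask, table: FeatureTable, partitions: PartitionSet) -> float:
    """One-off fitness of a mask (see :class:`FitnessEvaluator`)."""
    return FitnessEvaluator(table, partitions)(np.asarray(mask, dtype=bool))


def _tournament(fit: np.ndarray, size: int,
                rng: np.random.Generator) -> int:
    cand = rng.integers(0, fit.size, size=size)
    return int(cand[np.argmax(fit[cand])])


def evolve_generation(population: np.ndarray, fit: np.ndarray,
                      config: GAConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """One generation: elitism, tournament selection, arithmetic
    crossover, uniform mutation.  Children's genes stay inside the
    interval spanned by their parents' genes (convexity of arithmetic
    crossover)."""
    n_pop, n_genes = population.shape
    order = np.argsort(fit)[::-1]
    new = np.empty_like(population)
    n_elite = min(config.elite_count, n_pop)
    new[:n_elite] = population[order[:n_elite]]
    i = n_elite
    while i < n_pop:
        p1 = population[_tournament(fit, config.tournament_size, rng)]
        p2 = population[_tournament(fit, config.tournament_size, rng)]
        if rng.uniform() < config.crossover_prob:
            if config.binary_crossover:
                take = rng.uniform(size=n_genes) < 0.5
                c1 = np.where(take, p1, p2)
                c2 = np.where(take, p2, p1)
            else:
                lam = rng.uniform()
                c1 = lam * p1 + (1.0 - lam) * p2
                c2 = lam * p2 + (1.0 - lam) * p1
        else:
            c1, c2 = p1.copy(), p2.copy()
        for child in (c1, c2):
            if i >= n_pop:
                break
            mut = rng.uniform(size=n_genes) < config.mutation_prob
            if mut.any():
                child = child.copy()
                child[mut] = rng.uniform(size=int(mut.sum()))
            new[i] = child
            i += 1
    return new


def run_ga(table: FeatureTable, partitions: PartitionSet,
           config: GAConfig) -> GARunResult:
    """Evolve feature masks until the stall criterion (or safety cap).

    Returns the best mask ever seen and the per-generation (best, mean)
    fitness history; deterministic given ``config.seed``.
    """
    if config.genome_length != table.X.shape[1]:
        raise ValueError("genome_length must equal the table's feature count")
    rng = np.random.default_rng(config.seed)
    evaluator = FitnessEvaluator(table, partitions)
    pop = rng.uniform(size=(config.population_size, config.genome_length))
    # guarantee evaluability: a chromosome with an empty mask scores -inf
    best_fit = NEG_INF
    best_mask = None
    history: list = []
    stall = 0
    gen = 0
    for gen in range(1, config.max_generations + 1):
        fit = np.array([evaluator(mask_of(g)) for g in pop])
        gen_best = float(fit.max())
        finite = fit[np.isfinite(fit)]
        history.append((max(gen_best, best_fit),
                        float(finite.mean()) if finite.size else NEG_INF))
        if gen_best > best_fit + config.fitness_tolerance:
            stall = 0
        else:
            stall += 1
        if gen_best > best_fit:
            best_fit = gen_best
            best_mask = mask_of(pop[int(np.argmax(fit))]).copy()
        if stall >= config.stall_generations:
            break
        pop = evolve_generation(pop, fit, config, rng)
    if best_mask is None:  # pragma: no cover - requires all-empty masks
        raise RuntimeError("no evaluable chromosome was produced")
    logger.info("GA finished after %d generations, best fitness %.4f "
                "(%d features)", gen, best_fit, int(best_mask.sum()))
    return GARunResult(best_mask=best_mask, best_fitness=best_fit,
                       history=history, generations_run=gen)


def exhaustive_best_mask(table: FeatureTable,
                         partitions: PartitionSet) -> tuple:
    """Brute-force optimum over all 2^N - 1 nonempty masks (small N only)."""
    n = table.X.shape[1]
    if n > 16:
        raise ValueError("exhaustive search is limited to N <= 16")
    evaluator = FitnessEvaluator(table, partitions)
    best, best_mask = NEG_INF, None
    for code in range(1, 2 ** n):
        mask = np.array([(code >> i) & 1 for i in range(n)], dtype=bool)
        f = evaluator(mask)
        if f > best:
            best, best_mask = f, mask
    return best_mask, best
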