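"""Island-model grouping genetic algorithm for fuzzy partitioning.

The search evolves variable-length individuals [U | g] with operators that
act at the *group* (cluster) level:

- rank-roulette parent selection with replacement (distinct parents);
- grouping crossover: a contiguous block of clusters is inherited verbatim
  from the first parent; each observation's remaining membership mass is
  shared among a block of the second parent's clusters proportionally to
  that parent's memberships; empty clusters are removed and tags renumbered;
- split mutation (one cluster's memberships split by a random fraction into
  two clusters) and merge mutation (two clusters' rows summed), both choosing
  clusters with probability proportional to fuzzy mass;
- a hill-climbing local search that redraws single membership columns from
  the flat simplex and keeps strict improvements;
- per-island elitism and occasional elitist migration between islands.

Crossover probability decays linearly over generations, mutation probability
grows, and local-search probability decays, so early generations explore and
late ones exploit. All randomness flows from one master seed through
per-island substreams, so serial and island-parallel execution agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chromosome import EMPTY_CLUSTER_TOL, FuzzyChromosome, repair_chromosome
from .config import GGAConfig, RunReport
from .dataset import Dataset
from .distances import DistanceSpec
from .errors import ConfigError, DegeneratePartitionError
from .objectives import RankFitness, evaluate_objective, rank_fitness

__all__ = [
    "Island",
    "adaptive_probability",
    "init_population",
    "select_parent_pair",
    "combine_parents",
    "apply_split",
    "crossover",
    "mutate_split",
    "mutate_merge",
    "local_search",
    "migrate",
    "run_island_gga",
]

_CROSSOVER_RETRIES = 10


@dataclass
class Island:
    """One subpopulation with its cached objective values and random stream."""

    population: list[FuzzyChromosome]
    values: np.ndarray
    rng: np.random.Generator

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.values))


def adaptive_probability(
    generation: int, total_generations: int, p_start: float, p_end: float
) -> float:
    """Linear schedule from p_start (generation 0) to p_end (generation TG)."""
    frac = generation / total_generations
    return p_start + frac * (p_end - p_start)


def _random_columns(rng: np.random.Generator, k: int, n: int) -> np.ndarray:
    """k x n membership matrix with columns drawn from the flat simplex."""
    return rng.dirichlet(np.ones(k), size=n).T


def init_population(
    dataset: Dataset, config: GGAConfig, rng: np.random.Generator
) -> list[FuzzyChromosome]:
    """Random initial individuals: k ~ U{k_min..k_init_max}, simplex columns."""
    if config.k_init_max < config.k_min:
        raise ConfigError("k_init_max < k_min")
    pop = []
    for _ in range(config.population_size):
        k = int(rng.integers(config.k_min, config.k_init_max + 1))
        chrom = FuzzyChromosome(_random_columns(rng, k, dataset.n_points))
        pop.append(repair_chromosome(chrom, dataset=dataset))
    return pop


def select_parent_pair(
    rank: RankFitness, rng: np.random.Generator
) -> tuple[int, int]:
    """Two roulette draws over the rank intervals, redrawn until distinct."""
    ia = int(rank.order[np.searchsorted(rank.intervals, rng.random())])
    ib = ia
    while ib == ia:
        ib = int(rank.order[np.searchsorted(rank.intervals, rng.random())])
    return ia, ib


def _segment(rng: np.random.Generator, k: int) -> tuple[int, int]:
    """Two crossing points bounding a nonempty contiguous group block."""
    a, b = sorted(rng.choice(k + 1, size=2, replace=False))
    return int(a), int(b)


def combine_parents(ua_selected: np.ndarray, ub_selected: np.ndarray) -> np.ndarray:
    """Raw crossover arithmetic, before repair.

    The first parent's selected cluster rows are copied verbatim; for each
    observation the remaining mass 1 - (first-parent selected mass) is shared
    among the second parent's selected rows proportionally to that parent's
    memberships (rows of zeros where the second parent holds no mass — the
    resulting column deficit is repair's job).
    """
    remaining = 1.0 - ua_selected.sum(axis=0)
    np.clip(remaining, 0.0, None, out=remaining)
    bmass = ub_selected.sum(axis=0)
    share = np.divide(
        remaining, bmass, out=np.zeros_like(remaining), where=bmass > 0
    )
    return np.vstack([ua_selected, ub_selected * share])


def apply_split(U: np.ndarray, target: int, rho: float) -> np.ndarray:
    """Split cluster row ``target`` by fraction ``rho``: the kept row becomes
    rho*u and a new last row (1-rho)*u; column sums are unchanged."""
    row = U[target]
    out = np.vstack([U, (1.0 - rho) * row])
    out[target] = rho * row
    return out


def crossover(
    parent_a: FuzzyChromosome,
    parent_b: FuzzyChromosome,
    dataset: Dataset,
    rng: np.random.Generator,
    spec: DistanceSpec | None = None,
    fuzzifier: float = 2.0,
    k_max: int | None = None,
) -> FuzzyChromosome:
    """Grouping crossover: A's block verbatim, B's block shares the remainder.

    For each observation the mass not claimed by the first parent's selected
    clusters is distributed over the second parent's selected clusters in
    proportion to that parent's memberships; observations the second parent
    gives zero mass keep a deficit that repair renormalizes (or, if no
    surviving cluster holds any of their mass, repair reassigns them crisply
    to the nearest centroid). If repair degenerates (k < 2) or the offspring
    exceeds ``k_max``, new crossing points are drawn (at most 10 times)
    before falling back to a copy of the first parent.
    """
    for _ in range(_CROSSOVER_RETRIES):
        a0, a1 = _segment(rng, parent_a.n_clusters)
        b0, b1 = _segment(rng, parent_b.n_clusters)
        child = combine_parents(
            parent_a.membership[a0:a1], parent_b.membership[b0:b1]
        )
        try:
            offspring = repair_chromosome(
                FuzzyChromosome(child),
                dataset=dataset,
                spec=spec,
                fuzzifier=fuzzifier,
                crisp_empty=True,
            )
        except DegeneratePartitionError:
            continue
        if k_max is not None and offspring.n_clusters > k_max:
            continue
        return offspring
    return parent_a.copy()


def mutate_split(
    chromosome: FuzzyChromosome,
    dataset: Dataset,
    rng: np.random.Generator,
    k_max: int,
) -> FuzzyChromosome:
    """Split one mass-proportionally chosen cluster by a random fraction.

    Every membership u of the chosen cluster becomes rho*u in the kept
    cluster and (1-rho)*u in a new cluster tagged k+1; column sums are
    unchanged. No-op at k = k_max.
    """
    k = chromosome.n_clusters
    if k >= k_max:
        return chromosome
    mass = chromosome.membership.sum(axis=1)
    target = int(rng.choice(k, p=mass / mass.sum()))
    rho = float(rng.random())
    out = FuzzyChromosome(apply_split(chromosome.membership, target, rho))
    if min(rho, 1.0 - rho) * mass[target] < EMPTY_CLUSTER_TOL:
        out = repair_chromosome(out, dataset=dataset)  # degenerate fraction
    return out


def mutate_merge(
    chromosome: FuzzyChromosome, rng: np.random.Generator, k_min: int
) -> FuzzyChromosome:
    """Merge two mass-proportionally chosen clusters (rows summed). No-op at k_min."""
    k = chromosome.n_clusters
    if k <= k_min:
        return chromosome
    mass = chromosome.membership.sum(axis=1)
    i, j = rng.choice(k, size=2, replace=False, p=mass / mass.sum())
    i, j = int(min(i, j)), int(max(i, j))
    U = chromosome.membership.copy()
    U[i] += U[j]
    U = np.delete(U, j, axis=0)
    return FuzzyChromosome(U)


def local_search(
    chromosome: FuzzyChromosome,
    dataset: Dataset,
    objective_fn,
    trials: int,
    rng: np.random.Generator,
    spec: DistanceSpec | None = None,
    fuzzifier: float = 2.0,
    current_value: float | None = None,
) -> tuple[FuzzyChromosome, float]:
    """Membership hill climbing: keep a perturbation iff strictly better.

    Each trial proposes new membership columns for the observations: the
    columnwise-optimal assignment given the individual's current centroids
    and metrics (the standard fuzzy-partition update u_ij proportional to
    d_ij^(-2/(alpha-1)) under the active distance). The proposal is kept
    only when the *active* objective strictly decreases — the update is
    optimal for the compactness term alone, so the acceptance gate is what
    keeps separation-aware objectives (Xie-Beni, modified Davies-Bouldin)
    honest. Climbing stops at the first rejected proposal or after
    ``trials`` accepted sweeps. The returned objective value never exceeds
    the input's; ``rng`` is accepted for interface uniformity (the default
    proposal law is deterministic given the individual).
    """
    if spec is None:
        spec = DistanceSpec("euclidean")
    if trials <= 0:
        value = objective_fn(chromosome) if current_value is None else current_value
        return chromosome, value
    if current_value is None:
        current_value = objective_fn(chromosome)
    from .distances import build_cluster_model, sq_distances
    from .fcm import memberships_from_sq_distances

    U = chromosome.membership.copy()
    work = FuzzyChromosome(U)
    for _ in range(trials):
        try:
            model = build_cluster_model(dataset.points, U, fuzzifier, spec)
        except DegeneratePartitionError:
            break
        d2 = sq_distances(dataset.points, model, spec)
        old = U.copy()
        U[:] = memberships_from_sq_distances(d2, fuzzifier)
        trial_value = objective_fn(work)
        if trial_value < current_value:
            current_value = trial_value
        else:
            U[:] = old
            break
    return work, current_value


def migrate(
    islands: list[Island], p_migration: float, rng: np.random.Generator
) -> None:
    """Elitist migration: each island's best may replace a random non-elite
    individual of a random other island, with probability p_migration."""
    S = len(islands)
    if S < 2:
        return
    # all elites are identified before any replacement, so a migrant can
    # neither migrate onward in the same round nor evict a resident elite
    snapshot = [
        (isl.best_index, isl.population[isl.best_index].copy(), float(isl.values[isl.best_index]))
        for isl in islands
    ]
    for s in range(S):
        if rng.random() >= p_migration:
            continue
        dest_idx = int(rng.integers(S - 1))
        if dest_idx >= s:
            dest_idx += 1
        dest = islands[dest_idx]
        protected = snapshot[dest_idx][0]
        victim = int(rng.integers(len(dest.population) - 1))
        if victim >= protected:
            victim += 1
        _, best_chrom, best_value = snapshot[s]
        dest.population[victim] = best_chrom.copy()
        dest.values[victim] = best_value


def run_island_gga(dataset: Dataset, config: GGAConfig) -> RunReport:
    """Evolve S islands for TG generations and return the global best.

    Each generation, per island: rank the population, build xi offspring via
    roulette selection + crossover (probability P_c(j)) or parent copy, apply
    split and merge mutation serially (each with probability P_m(j)), then
    local search (probability P_b(j)); the island's previous best replaces
    the worst offspring (elitism); finally islands exchange elites with
    probability p_migration. Fully reproducible from ``config.seed``.
    """
    spec = DistanceSpec(config.distance, config.covariance_regularizer)
    alpha = config.fuzzifier

    def safe_eval(chrom: FuzzyChromosome) -> float:
        try:
            return evaluate_objective(dataset, chrom, config.objective, spec, alpha)
        except DegeneratePartitionError:
            return np.inf

    islands = []
    for s in range(config.n_islands):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(s,))
        )
        pop = init_population(dataset, config, rng)
        values = np.array([safe_eval(c) for c in pop])
        islands.append(Island(population=pop, values=values, rng=rng))
    migration_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(config.n_islands,))
    )

    TG = config.total_generations
    xi = config.population_size
    trace: list[tuple[int, float, int]] = []
    for gen in range(TG):
        p_c = adaptive_probability(
            gen, TG, config.p_crossover_initial, config.p_crossover_final
        )
        p_m = adaptive_probability(
            gen, TG, config.p_mutation_initial, config.p_mutation_final
        )
        p_b = adaptive_probability(
            gen, TG, config.p_local_initial, config.p_local_final
        )
        for isl in islands:
            rng = isl.rng
            rank = rank_fitness(isl.values)
            elite_idx = isl.best_index
            elite = isl.population[elite_idx]
            elite_value = float(isl.values[elite_idx])
            new_pop: list[FuzzyChromosome] = []
            new_values = np.empty(xi)
            for slot in range(xi):
                ia, ib = select_parent_pair(rank, rng)
                value: float | None
                if rng.random() < p_c:
                    child = crossover(
                        isl.population[ia],
                        isl.population[ib],
                        dataset,
                        rng,
                        spec=spec,
                        fuzzifier=alpha,
                        k_max=config.k_max,
                    )
                    value = None
                else:
                    child = isl.population[ia].copy()
                    value = float(isl.values[ia])
                if rng.random() < p_m:
                    mutated = mutate_split(child, dataset, rng, config.k_max)
                    if mutated is not child:
                        child, value = mutated, None
                if rng.random() < p_m:
                    mutated = mutate_merge(child, rng, config.k_min)
                    if mutated is not child:
                        child, value = mutated, None
                if rng.random() < p_b and config.local_search_trials > 0:
                    child, value = local_search(
                        child,
                        dataset,
                        safe_eval,
                        config.local_search_trials,
                        rng,
                        spec=spec,
                        fuzzifier=alpha,
                        current_value=value,
                    )
                if value is None:
                    value = safe_eval(child)
                new_pop.append(child)
                new_values[slot] = value
            worst = int(np.argmax(new_values))
            new_pop[worst] = elite.copy()
            new_values[worst] = elite_value
            isl.population = new_pop
            isl.values = new_values
        migrate(islands, config.p_migration, migration_rng)

        bests = [(float(i.values[i.best_index]), i) for i in islands]
        best_val, best_isl = min(bests, key=lambda t: t[0])
        best_k = best_isl.population[best_isl.best_index].n_clusters
        trace.append((gen + 1, best_val, best_k))

    best_val, best_isl = min(
        ((float(i.values[i.best_index]), i) for i in islands), key=lambda t: t[0]
    )
    best = best_isl.population[best_isl.best_index]
    return RunReport(
        best=best.copy(),
        best_objective=best_val,
        best_n_clusters=best.n_clusters,
        trace=trace,
        seed=config.seed,
        config=config.to_dict(),
    )
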