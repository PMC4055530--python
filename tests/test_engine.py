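import numpy as np
import pytest

from fuzzgga import Dataset, FuzzyChromosome, GGAConfig
from fuzzgga.distances import DistanceSpec
from fuzzgga.engine import (
    Island,
    adaptive_probability,
    apply_split,
    combine_parents,
    crossover,
    init_population,
    local_search,
    migrate,
    mutate_merge,
    mutate_split,
    run_island_gga,
    select_parent_pair,
)
from fuzzgga.objectives import evaluate_objective, rank_fitness

from conftest import random_valid_chromosome


@pytest.fixture
def blobs(rng):
    """Two tight, well-separated 2-D blobs of 10 points each."""
    X = np.vstack(
        [
            rng.normal(size=(10, 2)) * 0.2 + [0, 0],
            rng.normal(size=(10, 2)) * 0.2 + [6, 6],
        ]
    )
    return Dataset(points=X, labels=np.repeat([1, 2], 10))


class TestAdaptiveProbability:
    def test_schedule_endpoints_and_midpoint(self):
        assert adaptive_probability(0, 400, 0.8, 0.6) == pytest.approx(0.8)
        assert adaptive_probability(400, 400, 0.8, 0.6) == pytest.approx(0.6)
        assert adaptive_probability(200, 400, 0.05, 0.1) == pytest.approx(0.075)


class TestInitPopulation:
    def test_forced_k_range(self, blobs, rng):
        cfg = GGAConfig(k_min=2, k_init_max=2, population_size=8)
        pop = init_population(blobs, cfg, rng)
        assert all(c.n_clusters == 2 for c in pop)

    def test_columns_sum_to_one_and_valid(self, blobs, rng):
        cfg = GGAConfig(population_size=10)
        for chrom in init_population(blobs, cfg, rng):
            chrom.validate()

    def test_seeded_determinism(self, blobs):
        cfg = GGAConfig(population_size=6)
        a = init_population(blobs, cfg, np.random.default_rng(7))
        b = init_population(blobs, cfg, np.random.default_rng(7))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.membership, y.membership)


class TestSelection:
    def test_pair_always_distinct(self, rng):
        rank = rank_fitness([1.0, 2.0])
        for _ in range(50):
            ia, ib = select_parent_pair(rank, rng)
            assert {ia, ib} == {0, 1}

    def test_draw_half_lands_on_second_ranked(self):
        # intervals for 5 ranked individuals: 0.333|0.6|0.8|0.933|1.0
        rank = rank_fitness([10.0, 20.0, 30.0, 40.0, 50.0])
        idx = rank.order[np.searchsorted(rank.intervals, 0.5)]
        assert idx == 1  # second best by objective value

    def test_best_selected_one_third_of_the_time(self, rng):
        rank = rank_fitness([5.0, 1.0, 2.0, 3.0, 4.0])
        draws = np.searchsorted(rank.intervals, rng.random(100_000))
        freq = np.mean(rank.order[draws] == 1)  # individual 1 is the best
        sigma = np.sqrt((1 / 3) * (2 / 3) / 100_000)
        assert abs(freq - 1 / 3) < 3 * sigma


class TestCrossover:
    def test_combine_matches_worked_reassignment(self):
        # frozen from the published worked example: first-parent block rows
        # at observations (x12, x14, x1) leave remainders (0.2, 0.4, 1.0)
        # shared proportionally among the second parent's block
        ua = np.array([[0.0, 0.2, 0.0], [0.8, 0.4, 0.0]])
        ub = np.array([[0.6, 0.7, 0.8], [0.4, 0.1, 0.0]])
        child = combine_parents(ua, ub)
        np.testing.assert_allclose(child[2], [0.12, 0.35, 1.0])
        np.testing.assert_allclose(child[3], [0.08, 0.05, 0.0])

    def test_combine_two_point_example(self):
        # second parent: a single all-ones cluster absorbs the remainder
        ua = np.array([[0.7, 0.3]])
        ub = np.array([[1.0, 1.0]])
        child = combine_parents(ua, ub)
        np.testing.assert_allclose(child, [[0.7, 0.3], [0.3, 0.7]])

    def test_full_segment_of_identical_parent_is_absorbing(self, blobs, rng):
        parent = random_valid_chromosome(rng, 2, blobs.n_points)
        child = combine_parents(parent.membership, parent.membership[:0])
        np.testing.assert_allclose(child, parent.membership)

    def test_offspring_always_valid_and_bounded(self, blobs, rng):
        cfg = GGAConfig()
        for _ in range(50):
            ka, kb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            a = random_valid_chromosome(rng, ka, blobs.n_points)
            b = random_valid_chromosome(rng, kb, blobs.n_points)
            child = crossover(a, b, blobs, rng, k_max=cfg.k_max)
            child.validate()
            assert child.n_clusters <= cfg.k_max


class TestMutations:
    def test_split_worked_example_fraction(self):
        U = np.array([[1.0, 0.0, 0.8], [0.0, 1.0, 0.2]])
        out = apply_split(U, target=0, rho=0.4)
        np.testing.assert_allclose(out[0], [0.4, 0.0, 0.32])
        np.testing.assert_allclose(out[2], [0.6, 0.0, 0.48])

    def test_split_conserves_columns_and_increments_k(self, rng):
        chrom = random_valid_chromosome(rng, 3, 12)
        out = mutate_split(chrom, None, rng, k_max=10)
        assert out.n_clusters == 4
        np.testing.assert_allclose(
            out.membership.sum(0), chrom.membership.sum(0), atol=1e-12
        )

    def test_split_noop_at_k_max(self, rng):
        chrom = random_valid_chromosome(rng, 3, 12)
        assert mutate_split(chrom, None, rng, k_max=3) is chrom

    def test_merge_sums_rows_and_relabels(self, rng):
        U = np.array(
            [[0.3, 0.5], [0.2, 0.1], [0.4, 0.2], [0.1, 0.2]]
        )
        chrom = FuzzyChromosome(U)
        merged = None
        for _ in range(40):  # find a draw that merges rows 1 and 3
            out = mutate_merge(chrom, rng, k_min=2)
            assert out.n_clusters == 3
            np.testing.assert_array_equal(out.groups, [1, 2, 3])
            np.testing.assert_allclose(out.membership.sum(0), U.sum(0))
            merged = out
        assert merged is not None

    def test_merge_specific_rows(self):
        U = np.array([[0.3, 0.5], [0.2, 0.1]])
        chrom = FuzzyChromosome(np.vstack([U, [[0.5, 0.4]]]))

        class FixedRng:
            def choice(self, k, size=None, replace=True, p=None):
                return np.array([0, 1])

        out = mutate_merge(chrom, FixedRng(), k_min=2)
        np.testing.assert_allclose(out.membership[0], [0.5, 0.6])

    def test_merge_noop_at_k_min(self, rng):
        chrom = random_valid_chromosome(rng, 2, 12)
        assert mutate_merge(chrom, rng, k_min=2) is chrom


class TestLocalSearch:
    def _objective_fn(self, ds):
        spec = DistanceSpec("euclidean")
        return lambda c: evaluate_objective(ds, c, "fsse", spec)

    def test_zero_trials_is_identity(self, blobs, rng):
        chrom = random_valid_chromosome(rng, 2, blobs.n_points)
        out, val = local_search(chrom, blobs, self._objective_fn(blobs), 0, rng)
        np.testing.assert_array_equal(out.membership, chrom.membership)

    def test_objective_never_increases(self, blobs, rng):
        fn = self._objective_fn(blobs)
        for _ in range(10):
            chrom = random_valid_chromosome(rng, 3, blobs.n_points)
            before = fn(chrom)
            _, after = local_search(chrom, blobs, fn, 5, rng)
            assert after <= before + 1e-12

    def test_misassigned_point_gets_repaired(self, rng):
        # two obvious pairs with one point crisply assigned to the far cluster
        ds = Dataset(points=np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 0.0], [5.1, 0.0]]))
        fn = self._objective_fn(ds)
        fixed = 0
        for seed in range(20):
            U = np.array(
                [[1.0, 0.0, 0.0, 1.0], [0.0, 1.0, 1.0, 0.0]]
            )  # x2 and x4 swapped across clusters
            chrom = FuzzyChromosome(U)
            out, val = local_search(
                chrom, ds, fn, 50, np.random.default_rng(seed)
            )
            if val < fn(chrom) - 1e-9:
                fixed += 1
        assert fixed / 20 > 0.9


class TestMigration:
    def _islands(self, rng, values_a, values_b):
        pops = []
        for values in (values_a, values_b):
            pop = [random_valid_chromosome(rng, 2, 6) for _ in values]
            pops.append(
                Island(population=pop, values=np.array(values, dtype=float), rng=rng)
            )
        return pops

    def test_zero_probability_changes_nothing(self, rng):
        islands = self._islands(rng, [1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        before = [[c.membership.copy() for c in isl.population] for isl in islands]
        migrate(islands, 0.0, rng)
        for isl, prev in zip(islands, before):
            for chrom, old in zip(isl.population, prev):
                np.testing.assert_array_equal(chrom.membership, old)

    def test_probability_one_two_islands_swap_best(self, rng):
        islands = self._islands(rng, [1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        best_a = islands[0].population[0].membership.copy()
        best_b = islands[1].population[0].membership.copy()
        migrate(islands, 1.0, rng)
        assert all(len(isl.population) == 3 for isl in islands)
        assert any(
            np.array_equal(c.membership, best_b) for c in islands[0].population
        )
        assert any(
            np.array_equal(c.membership, best_a) for c in islands[1].population
        )
        # the resident elite is never the victim
        assert np.array_equal(islands[0].population[0].membership, best_a)
        assert np.array_equal(islands[1].population[0].membership, best_b)


class TestRunIslandGGA:
    CFG = dict(
        population_size=8,
        n_islands=2,
        total_generations=12,
        k_init_max=4,
        k_max=6,
        local_search_trials=3,
    )

    def test_trace_non_increasing_and_best_consistent(self, blobs):
        report = run_island_gga(blobs, GGAConfig(seed=3, **self.CFG))
        objs = [o for _, o, _ in report.trace]
        assert len(report.trace) == self.CFG["total_generations"]
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))
        assert report.best_objective == pytest.approx(min(objs))
        report.best.validate()
        assert 2 <= report.best_n_clusters <= self.CFG["k_max"]

    def test_same_seed_identical_report(self, blobs):
        r1 = run_island_gga(blobs, GGAConfig(seed=11, **self.CFG))
        r2 = run_island_gga(blobs, GGAConfig(seed=11, **self.CFG))
        np.testing.assert_array_equal(r1.best.membership, r2.best.membership)
        assert r1.trace == r2.trace

    def test_zero_operator_probabilities_keep_initial_best(self, blobs):
        cfg = GGAConfig(
            seed=5,
            p_crossover_initial=0.0,
            p_crossover_final=0.0,
            p_mutation_initial=0.0,
            p_mutation_final=0.0,
            p_local_initial=0.0,
            p_local_final=0.0,
            p_migration=0.0,
            **self.CFG,
        )
        report = run_island_gga(blobs, cfg)
        objs = [o for _, o, _ in report.trace]
        assert objs[0] == pytest.approx(objs[-1])

    def test_separated_blobs_are_recovered(self, blobs):
        report = run_island_gga(blobs, GGAConfig(seed=1, **self.CFG))
        from fuzzgga import defuzzify, rand_index

        assert report.best_n_clusters == 2
        assert rand_index(defuzzify(report.best), blobs.labels) == pytest.approx(1.0)


def test_operators_preserve_partition_constraints(rng):
    """1e3 random operator applications never violate column-stochasticity
    or the non-empty-cluster constraint."""
    ds = Dataset(points=rng.normal(size=(15, 2)))
    for _ in range(250):
        ka, kb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        a = random_valid_chromosome(rng, ka, 15)
        b = random_valid_chromosome(rng, kb, 15)
        child = crossover(a, b, ds, rng, k_max=8)
        child.validate()
        split = mutate_split(child, ds, rng, k_max=8)
        split.validate()
        merged = mutate_merge(split, rng, k_min=2)
        merged.validate()
        again = mutate_merge(merged, rng, k_min=2)
        again.validate()
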