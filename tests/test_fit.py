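"""NSGA-II operators and the weighting-coefficient model."""

import numpy as np
import pandas as pd
import pytest

from vesseltort.fit import (
    GeneBounds,
    SegmentDataset,
    TortuosityWeightModel,
    crowding_distance,
    evaluate_genome,
    nondominated_sort,
    polynomial_mutation,
    run_nsga2,
    sbx_crossover,
)

BOUNDS = GeneBounds()


def brute_force_fronts(obj):
    """O(n^2) dominance oracle (maximization)."""
    n = len(obj)
    remaining = set(range(n))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            dominated = any(
                j != i
                and all(obj[j][k] >= obj[i][k] for k in range(2))
                and any(obj[j][k] > obj[i][k] for k in range(2))
                for j in remaining
            )
            if not dominated:
                front.append(i)
        fronts.append(sorted(front))
        remaining -= set(front)
    return fronts


def toy_tables(taus_per_image):
    tables = []
    for taus in taus_per_image:
        n = len(taus)
        tables.append(
            pd.DataFrame(
                {
                    "L_c": np.full(n, 50),
                    "f_av": np.full(n, 0.5),
                    "f_cal": np.full(n, 6.0),
                    "f_dod": np.full(n, 100.0),
                    "f_dfov": np.full(n, 150.0),
                    "tortuosity": taus,
                }
            )
        )
    return tables


class TestNondominatedSort:
    def test_spec_example(self):
        obj = np.array([[0.9, 0.5], [0.5, 0.9], [0.4, 0.4]])
        fronts = nondominated_sort(obj)
        assert sorted(fronts[0].tolist()) == [0, 1]
        assert fronts[1].tolist() == [2]

    def test_single_and_duplicates(self):
        assert nondominated_sort(np.array([[0.5, 0.5]]))[0].tolist() == [0]
        dup = np.tile([[0.3, 0.7]], (4, 1))
        fronts = nondominated_sort(dup)
        assert len(fronts) == 1 and len(fronts[0]) == 4

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            obj = rng.random((int(rng.integers(2, 50)), 2))
            got = [sorted(f.tolist()) for f in nondominated_sort(obj)]
            assert got == brute_force_fronts(obj.tolist())


class TestCrowdingDistance:
    def test_front_of_two_all_infinite(self):
        d = crowding_distance(np.array([[0.2, 0.8], [0.6, 0.3]]))
        assert np.isinf(d).all()

    def test_canonical_three_point_front(self):
        d = crowding_distance(np.array([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]]))
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_identical_objective_vectors_interior_zero(self):
        obj = np.tile([[0.5, 0.5]], (5, 1))
        d = crowding_distance(obj)
        assert np.isinf(d).sum() == 2  # one boundary per objective sort
        assert (d[~np.isinf(d)] == 0).all()


class TestSBXCrossover:
    def test_identical_parents_identical_offspring(self, rng):
        p = np.array([0.5, 0.3, 0.05, 0.02, 0.01])
        c1, c2 = sbx_crossover(p, p, BOUNDS, rng)
        np.testing.assert_allclose(c1, p)
        np.testing.assert_allclose(c2, p)

    def test_offspring_within_bounds(self, rng):
        for _ in range(200):
            p1 = BOUNDS.lower + rng.random(5) * (BOUNDS.upper - BOUNDS.lower)
            p2 = BOUNDS.lower + rng.random(5) * (BOUNDS.upper - BOUNDS.lower)
            for c in sbx_crossover(p1, p2, BOUNDS, rng):
                assert (c >= BOUNDS.lower - 1e-12).all()
                assert (c <= BOUNDS.upper + 1e-12).all()

    def test_mean_preservation_monte_carlo(self):
        rng = np.random.default_rng(5)
        p1 = np.array([0.2, 0.4, 0.03, 0.05, 0.02])
        p2 = np.array([0.8, 0.6, 0.07, 0.02, 0.06])
        sums = np.zeros(5)
        n = 10_000
        for _ in range(n):
            c1, c2 = sbx_crossover(p1, p2, BOUNDS, rng)
            sums += (c1 + c2) / 2
        means = sums / n
        midpoint = (p1 + p2) / 2
        # offspring midpoint equals parent midpoint per pair up to boundary
        # clipping; 3 standard errors of the per-gene spread
        se = 3 * np.abs(p1 - p2) * 0.05 / np.sqrt(n)
        assert (np.abs(means - midpoint) <= np.maximum(se, 1e-3)).all()


class TestPolynomialMutation:
    def test_stays_within_bounds_and_lower_bound_moves_up(self, rng):
        g = BOUNDS.lower.copy()
        for _ in range(300):
            m = polynomial_mutation(g, BOUNDS, rng, p_m=1.0, per_gene_rate=1.0)
            assert (m >= BOUNDS.lower).all() and (m <= BOUNDS.upper).all()

    def test_symmetric_about_midrange_gene(self):
        rng = np.random.default_rng(9)
        g = np.array([0.5, 0.5, 0.05, 0.05, 0.05])
        deltas = []
        for _ in range(10_000):
            m = polynomial_mutation(g, BOUNDS, rng, p_m=1.0, per_gene_rate=1.0)
            deltas.append(m[0] - 0.5)
        deltas = np.asarray(deltas)
        assert abs(deltas.mean()) <= 3 * deltas.std() / np.sqrt(len(deltas))


class TestEvaluateAndRun:
    def _dataset(self):
        # even images straight (label 0), odd images tortuous (label 1)
        taus = [[0.0001, 0.0002] if i % 2 == 0 else [0.02, 0.05] for i in range(12)]
        return SegmentDataset(toy_tables(taus), [i % 2 for i in range(12)])

    def test_degenerate_genomes(self):
        ds = self._dataset()
        all_positive = np.array([0.5, 0.0, 0.0, 0.0, 0.0])  # phi = 0, tau > 0
        assert evaluate_genome(all_positive, ds) == (1.0, 0.0)
        all_negative = np.array([0.5, 0.0, 0.0, 0.0, 0.1])  # huge phi
        assert evaluate_genome(all_negative, ds) == (0.0, 1.0)

    def test_known_genome_perfect_on_its_own_labels(self):
        taus = [[0.001 * (i + 1), 0.002 * (i + 1)] for i in range(10)]
        tables = toy_tables(taus)
        genome = np.array([0.5, 0.0, 0.0, 0.0, 0.008])
        ds_unlab = SegmentDataset(tables)
        scores = ds_unlab.scores(genome[None, :])[0]
        labels = (scores > genome[4]).astype(int).tolist()
        ds = SegmentDataset(tables, labels)
        assert evaluate_genome(genome, ds) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            SegmentDataset(toy_tables([[0.01], [0.02]]), [1, 1])

    def test_separable_dataset_reaches_perfect_corner(self):
        front, info = run_nsga2(self._dataset(), pop_size=40, seed=1, max_generations=40)
        best = max(front, key=lambda i: i.sensitivity + i.specificity)
        assert (best.sensitivity, best.specificity) == (1.0, 1.0)

    def test_same_seed_bit_identical(self):
        ds = self._dataset()
        f1, _ = run_nsga2(ds, pop_size=20, seed=7, max_generations=15, stall_generations=50)
        f2, _ = run_nsga2(ds, pop_size=20, seed=7, max_generations=15, stall_generations=50)
        assert len(f1) == len(f2)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.genome, b.genome)

    def test_elitism_best_objectives_never_decrease(self):
        ds = self._dataset()
        rng = np.random.default_rng(3)
        # track best objectives across manual generations via repeated runs
        best_prev = None
        for gens in (2, 5, 10):
            front, _ = run_nsga2(ds, pop_size=20, seed=11, max_generations=gens,
                                 stall_generations=100)
            best = (
                max(i.sensitivity for i in front),
                max(i.specificity for i in front),
            )
            if best_prev is not None:
                assert best[0] >= best_prev[0] - 1e-12
                assert best[1] >= best_prev[1] - 1e-12
            best_prev = best

    def test_model_results_summary_and_front_table(self):
        ds = self._dataset()
        res = TortuosityWeightModel(ds).fit(pop_size=20, seed=2, max_generations=10)
        text = res.summary()
        assert "Pareto front" in text and "omega_av" in text
        table = res.front_table
        assert {"sensitivity", "specificity", "balanced_accuracy"} <= set(table.columns)
        assert (table["balanced_accuracy"].diff().dropna() <= 1e-12).all()
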