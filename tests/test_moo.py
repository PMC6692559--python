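import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agrimoo.moo import (
    Frontier,
    OptimizerConfig,
    crowding_distance,
    de_trial_vector,
    dominates,
    evolve,
    fast_nondominated_sort,
    seed_initial_population,
    trim_frontier,
)
from agrimoo.surrogate import (
    GENOME_LENGTH,
    N_APPLICATIONS,
    ManagementPlan,
    ValidationError,
)

MIN2 = np.array([-1, -1])


def brute_force_fronts(objs, directions):
    """Independent oracle: repeatedly peel the dominated-by-nobody set
    using the scalar dominance predicate."""
    n = len(objs)
    remaining = set(range(n))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(dominates(objs[j], objs[i], directions) for j in remaining if j != i)
        ]
        fronts.append(sorted(front))
        remaining -= set(front)
    return fronts


class TestDominates:
    def test_equal_not_dominating(self):
        assert not dominates([1, 1], [1, 1], MIN2)

    def test_better_everywhere(self):
        assert dominates([0, 0], [1, 1], MIN2)

    def test_incomparable(self):
        assert not dominates([0, 2], [1, 1], MIN2)
        assert not dominates([1, 1], [0, 2], MIN2)

    def test_direction_aware(self):
        maxmin = np.array([1, -1])
        assert dominates([5, 0], [4, 1], maxmin)
        assert not dominates([4, 0], [5, 0], maxmin)

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            dominates([1, 2, 3], [1, 2], MIN2)


class TestSort:
    def test_single_point(self):
        fronts, ranks = fast_nondominated_sort([[1.0, 2.0]], MIN2)
        assert len(fronts) == 1 and ranks[0] == 0

    def test_chain_of_three(self):
        objs = [[3, 3], [2, 2], [1, 1]]
        fronts, ranks = fast_nondominated_sort(objs, MIN2)
        assert [f.tolist() for f in fronts] == [[2], [1], [0]]
        assert ranks.tolist() == [2, 1, 0]

    def test_oracle_random_4obj(self):
        rng = np.random.default_rng(0)
        directions = np.array([1, -1, 1, -1])
        objs = rng.random((50, 4))
        fronts, ranks = fast_nondominated_sort(objs, directions)
        oracle = brute_force_fronts(objs, directions)
        assert [sorted(f.tolist()) for f in fronts] == oracle

    def test_oracle_with_duplicates(self):
        rng = np.random.default_rng(1)
        objs = rng.integers(0, 3, size=(40, 3)).astype(float)  # heavy ties
        directions = np.array([-1, -1, -1])
        fronts, _ = fast_nondominated_sort(objs, directions)
        assert [sorted(f.tolist()) for f in fronts] == brute_force_fronts(objs, directions)

    @settings(max_examples=30, deadline=None)
    @given(
        n=st.integers(2, 25),
        m=st.integers(2, 6),
        seed=st.integers(0, 10_000),
    )
    def test_oracle_property(self, n, m, seed):
        rng = np.random.default_rng(seed)
        objs = np.round(rng.random((n, m)), 1)  # rounding forces duplicates
        directions = rng.choice([-1, 1], size=m)
        fronts, ranks = fast_nondominated_sort(objs, directions)
        assert sorted(np.concatenate(fronts).tolist()) == list(range(n))
        assert [sorted(f.tolist()) for f in fronts] == brute_force_fronts(objs, directions)


class TestCrowding:
    def test_two_points_infinite(self):
        d = crowding_distance([[0, 1], [1, 0]])
        assert np.all(np.isinf(d))

    def test_three_collinear_equally_spaced(self):
        d = crowding_distance([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_identical_objectives_zero_interior(self):
        d = crowding_distance([[1.0, 1.0]] * 5)
        assert np.isinf(d).sum() >= 2
        assert np.all(d[np.isfinite(d)] == 0.0)


class TestDETrial:
    def _pop(self, rng, n=10, d=5):
        return rng.random((n, d)) * 10

    def test_f0_cr1_copies_donor(self):
        rng = np.random.default_rng(0)
        pop = self._pop(rng)
        cfg = OptimizerConfig(pop_size=10, de_F=0.0, de_CR=1.0, seed=0)
        trial = de_trial_vector(0, pop, cfg, np.random.default_rng(1),
                                np.zeros(5), np.full(5, 10.0))
        matches = [i for i in range(1, 10) if np.allclose(trial, pop[i])]
        assert len(matches) == 1

    def test_cr0_one_gene_from_donor(self):
        rng = np.random.default_rng(2)
        pop = self._pop(rng)
        cfg = OptimizerConfig(pop_size=10, de_F=0.7, de_CR=0.0, seed=0)
        trial = de_trial_vector(3, pop, cfg, np.random.default_rng(3),
                                np.zeros(5), np.full(5, 10.0))
        assert (trial != pop[3]).sum() == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        pop = self._pop(rng)
        cfg = OptimizerConfig(pop_size=10, de_F=0.8, de_CR=0.9, seed=0)
        t1 = de_trial_vector(2, pop, cfg, np.random.default_rng(9), np.zeros(5), np.full(5, 10.0))
        t2 = de_trial_vector(2, pop, cfg, np.random.default_rng(9), np.zeros(5), np.full(5, 10.0))
        np.testing.assert_array_equal(t1, t2)

    def test_bounds_and_integer_repair(self):
        pop = np.array([[0.0, 0.0], [100.0, 3.0], [100.0, 3.0], [0.0, 0.0], [50.0, 1.4]])
        cfg = OptimizerConfig(pop_size=5, de_F=2.0, de_CR=1.0, seed=0)
        imask = np.array([False, True])
        for s in range(20):
            t = de_trial_vector(0, pop, cfg, np.random.default_rng(s),
                                np.array([0.0, 0.0]), np.array([100.0, 3.0]), imask)
            assert 0 <= t[0] <= 100
            assert t[1] in (0.0, 1.0, 2.0, 3.0)

    def test_population_too_small(self):
        cfg = OptimizerConfig(pop_size=4, seed=0)
        with pytest.raises(ValueError):
            de_trial_vector(0, np.zeros((3, 2)), cfg, np.random.default_rng(0),
                            np.zeros(2), np.ones(2))


class TestSeeding:
    def test_half_sparse(self):
        cfg = OptimizerConfig(pop_size=100, sparse_seed_fraction=0.5, seed=0)
        genomes = seed_initial_population(cfg)
        zero_counts = (genomes[:, :N_APPLICATIONS] == 0.0).sum(axis=1)
        sparse = zero_counts >= 6
        assert sparse.sum() == 50
        assert set(zero_counts[sparse]) <= {6, 7, 8}

    def test_no_sparse(self):
        cfg = OptimizerConfig(pop_size=60, sparse_seed_fraction=0.0, seed=0)
        genomes = seed_initial_population(cfg)
        zero_counts = (genomes[:, :N_APPLICATIONS] == 0.0).sum(axis=1)
        assert (zero_counts == 0).all()  # a.s. for uniform draws

    def test_zero_count_histogram(self):
        cfg = OptimizerConfig(pop_size=400, sparse_seed_fraction=0.5, seed=1)
        genomes = seed_initial_population(cfg)
        zero_counts = (genomes[:, :N_APPLICATIONS] == 0.0).sum(axis=1)
        counts = zero_counts[zero_counts >= 6]
        assert len(counts) == 200
        for z in (6, 7, 8):
            assert (counts == z).sum() > 30  # roughly uniform over {6,7,8}

    def test_user_seeds_first(self):
        cfg = OptimizerConfig(pop_size=10, sparse_seed_fraction=0.2, seed=0)
        plan = ManagementPlan(n_rates=(1.0,) * 9, fym_amount=2.0)
        genomes = seed_initial_population(cfg, [plan])
        np.testing.assert_array_equal(genomes[0], plan.to_genome())

    def test_invalid_user_seed_rejected(self):
        cfg = OptimizerConfig(pop_size=10, seed=0)
        bad = ManagementPlan(n_rates=(1.0,) * 9)
        object.__setattr__(bad, "fym_amount", 9.0)
        with pytest.raises(ValidationError):
            seed_initial_population(cfg, [bad])

    def test_bounds_respected(self):
        cfg = OptimizerConfig(pop_size=200, sparse_seed_fraction=0.5, seed=3)
        g = seed_initial_population(cfg)
        assert g.shape == (200, GENOME_LENGTH)
        assert (g[:, :9] >= 0).all() and (g[:, :9] <= 100).all()
        assert (g[:, 9] >= 0).all() and (g[:, 9] <= 3).all()
        assert np.isin(g[:, 10], [0, 1, 2, 3]).all()


class TestTrim:
    def _line_frontier(self, n):
        x = np.linspace(0, 1, n)
        objs = np.stack([x, 1 - x], axis=1)
        return Frontier(genomes=np.zeros((n, 1)), objectives=objs, directions=MIN2)

    def test_small_frontier_unchanged(self):
        f = self._line_frontier(50)
        assert trim_frontier(f, 100) is f

    def test_line_trim_keeps_extremes(self):
        f = self._line_frontier(200)
        t = trim_frontier(f, 100)
        assert len(t) == 100
        assert t.objectives[:, 0].min() == 0.0 and t.objectives[:, 0].max() == 1.0

    def test_output_still_nondominated(self):
        rng = np.random.default_rng(5)
        # random 2-d front: sort-filtered random points
        pts = rng.random((400, 2))
        fronts, _ = fast_nondominated_sort(pts, MIN2)
        objs = pts[fronts[0]]
        f = Frontier(genomes=np.zeros((len(objs), 1)), objectives=objs, directions=MIN2)
        t = trim_frontier(f, max(3, len(objs) // 2))
        fronts2, _ = fast_nondominated_sort(t.objectives, MIN2)
        assert len(fronts2) == 1


class TestEvolve:
    def test_deterministic(self):
        def f(x):
            return np.array([x[0], (x - 0.5).sum() ** 2])

        cfg = OptimizerConfig(pop_size=20, n_generations=15, seed=11, hv_every=0)
        r1 = evolve(f, MIN2, cfg, lower=np.zeros(4), upper=np.ones(4))
        r2 = evolve(f, MIN2, cfg, lower=np.zeros(4), upper=np.ones(4))
        np.testing.assert_array_equal(r1.frontier.genomes, r2.frontier.genomes)
        np.testing.assert_array_equal(r1.frontier.objectives, r2.frontier.objectives)

    def test_degenerate_single_objective(self):
        # second objective constant: collapses to unimodal minimization
        def f(x):
            return np.array([np.sum((x - 0.3) ** 2), 1.0])

        cfg = OptimizerConfig(pop_size=30, n_generations=60, de_F=0.5, seed=2, hv_every=0)
        res = evolve(f, MIN2, cfg, lower=np.zeros(3), upper=np.ones(3))
        best = res.frontier.objectives[:, 0].min()
        # grid-search oracle on the same box
        grid = np.linspace(0, 1, 21)
        oracle = min(
            np.sum((np.array([a, b, c]) - 0.3) ** 2)
            for a in grid
            for b in grid
            for c in grid
        )
        assert best <= oracle + 1e-6

    def test_elitism_best_never_worsens(self):
        def f(x):
            f1 = x[0]
            g = 1 + 9 * np.mean(x[1:])
            return np.array([f1, g * (1 - np.sqrt(f1 / g))])

        cfg = OptimizerConfig(pop_size=24, n_generations=40, seed=4, hv_every=0)
        res = evolve(f, MIN2, cfg, lower=np.zeros(6), upper=np.ones(6))
        best = np.array([h["best_minimized"] for h in res.history])
        diffs = np.diff(best, axis=0)
        assert (diffs <= 1e-12).all()

    def test_failed_evaluation_penalized(self):
        calls = {"n": 0}

        def f(x):
            calls["n"] += 1
            if calls["n"] == 5:
                raise RuntimeError("boom")
            return np.array([x[0], 1 - x[0]])

        cfg = OptimizerConfig(pop_size=8, n_generations=3, seed=0, hv_every=0)
        res = evolve(f, MIN2, cfg, lower=np.zeros(2), upper=np.ones(2))
        assert np.all(np.abs(res.frontier.objectives) < 1e17)

    def test_frontier_mutually_nondominated(self):
        def f(x):
            return np.array([x[0], 1 - x[0] + 0.1 * x[1]])

        cfg = OptimizerConfig(pop_size=16, n_generations=20, seed=6, hv_every=0)
        res = evolve(f, MIN2, cfg, lower=np.zeros(2), upper=np.ones(2))
        objs = res.frontier.objectives
        for i in range(len(objs)):
            for j in range(len(objs)):
                if i != j:
                    assert not dominates(objs[i], objs[j], MIN2)
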