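"""Unit and property tests for the continuous CGO optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from chaosfs import (
    CGOParams,
    SeedPopulation,
    alpha_formulas,
    box_counting_dimension,
    chaos_game_sierpinski,
    generate_seeds,
    handle_bounds,
    initialize_population,
    mean_group,
    optimize,
    random_search,
    replace_if_better,
    sample_alpha,
)


class ScriptedRNG:
    """Stub generator replaying scripted integer and uniform draws."""

    def __init__(self, integers=(), randoms=()):
        self._int = list(integers)
        self._rand = list(randoms)

    def integers(self, *args, **kwargs):
        return self._int.pop(0)

    def random(self, size=None):
        if size is None:
            return self._rand.pop(0)
        return np.array([self._rand.pop(0) for _ in range(int(size))])


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dim": 0},
            {"dim": 2, "population_size": 1},
            {"dim": 2, "max_iterations": 0},
            {"dim": 2, "lower_bound": 1.0, "upper_bound": 0.0},
            {"dim": 2, "lower_bound": -np.inf},
            {"dim": 2, "beta_gamma_domain": (1, 3)},
            {"dim": 2, "mean_group_size": 99},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CGOParams(**{"population_size": 5, "max_iterations": 3, **kwargs})

    def test_default_population_size_is_fifty(self):
        assert CGOParams(dim=4).population_size == 50

    def test_default_beta_gamma_domain(self):
        assert CGOParams(dim=4).beta_gamma_domain == (1, 2)


class TestInitialization:
    def test_uniform_within_bounds(self, rng):
        p = CGOParams(dim=3, population_size=2, rng_seed=0)
        pop = initialize_population(p, lambda x: 0.0)
        assert pop.positions.shape == (2, 3)
        assert np.all(pop.positions >= 0.0) and np.all(pop.positions <= 1.0)

    def test_degenerate_bounds_collapse(self):
        p = CGOParams(dim=4, population_size=3, lower_bound=0.5, upper_bound=0.5)
        pop = initialize_population(p, lambda x: float(x.sum()))
        assert np.all(pop.positions == 0.5)

    def test_default_population_has_fifty_rows(self):
        p = CGOParams(dim=2, rng_seed=1)
        pop = initialize_population(p, lambda x: float(x.sum()))
        assert pop.positions.shape[0] == 50

    def test_global_best_matches_minimum(self):
        p = CGOParams(dim=2, population_size=10, rng_seed=3)
        pop = initialize_population(p, lambda x: float(np.sum(x**2)))
        assert pop.global_best_fitness == pytest.approx(pop.fitness.min())


class TestAlpha:
    def test_four_formula_values_at_frozen_draws(self):
        assert alpha_formulas(0.5, 0.5) == (0.5, 1.0, 1.25, 0.75)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_always_in_open_interval_zero_two(self, seed):
        val = sample_alpha(np.random.default_rng(seed))
        assert 0.0 < val < 2.0

    def test_formula_choice_uniform(self):
        class Spy:
            def __init__(self):
                self.rng = np.random.default_rng(99)
                self.picks = []

            def integers(self, *a, **k):
                v = self.rng.integers(*a, **k)
                self.picks.append(int(v))
                return v

            def random(self, size=None):
                return self.rng.random(size)

        spy = Spy()
        for _ in range(100_000):
            sample_alpha(spy)
        counts = np.bincount(spy.picks, minlength=4)
        freqs = counts / counts.sum()
        assert np.all(np.abs(freqs - 0.25) < 0.02)
        assert chisquare(counts).pvalue > 0.001


class TestMeanGroup:
    def _pop(self, positions):
        positions = np.asarray(positions, float)
        fit = np.zeros(len(positions))
        return SeedPopulation(positions, fit, positions[0], 0.0)

    def test_full_subset_is_centroid(self):
        pop = self._pop([[0, 0], [1, 1], [2, 5]])
        got = mean_group(pop, np.random.default_rng(0), size=3)
        np.testing.assert_allclose(got, [1.0, 2.0])

    def test_singleton_subset_is_that_row(self):
        pop = self._pop([[3.0, 4.0], [5.0, 6.0]])
        got = mean_group(pop, np.random.default_rng(0), size=1)
        assert any(np.allclose(got, row) for row in pop.positions)

    def test_identical_rows_give_common_vector(self):
        pop = self._pop([[2.0, 2.0]] * 5)
        got = mean_group(pop, np.random.default_rng(7))
        np.testing.assert_allclose(got, [2.0, 2.0])

    def test_empty_population_rejected(self):
        pop = SeedPopulation(
            np.empty((0, 2)), np.empty(0), np.zeros(2), np.inf
        )
        with pytest.raises(ValueError):
            mean_group(pop, np.random.default_rng(0))


class TestGenerateSeeds:
    def test_fixed_point_when_vertices_coincide_and_die_equal(self):
        # script beta == gamma for all three points: bracket vanishes
        p = CGOParams(dim=2, population_size=5, lower_bound=-5, upper_bound=5)
        x = np.array([0.3, -0.7])
        rng = ScriptedRNG(
            integers=[0, 0, 0, 0, 1, 1, 0, 1, 1],  # (alpha-idx, beta, gamma) x3
            randoms=[0.5, 0.5, 0.5, 0.5, 0.5, 0.5,  # alpha R/eps draws x3
                     0.9, 0.1, 0.2],  # P4: subset mask (dim=2), one addition
        )
        seeds = generate_seeds(x, x, x, p, rng)
        np.testing.assert_allclose(seeds.p1, x)
        np.testing.assert_allclose(seeds.p2, x)
        np.testing.assert_allclose(seeds.p3, x)

    def test_direct_substitution_with_unit_coefficients(self):
        # alpha=1 (formula eps*R+1 with R->0 limit approximated by eps*0+1),
        # beta=gamma=1 via domain index 0
        p = CGOParams(dim=2, population_size=5, lower_bound=0.0, upper_bound=1.0)
        s = np.array([0.0, 0.0])
        g = np.array([1.0, 1.0])
        m = np.array([0.5, 0.5])
        rng = ScriptedRNG(
            integers=[2, 0, 0, 2, 0, 0, 2, 0, 0],
            randoms=[0.0, 1.0, 0.0, 1.0, 0.0, 1.0,  # R=0, eps=1 -> alpha=1
                     0.9, 0.1, 0.3],
        )
        seeds = generate_seeds(s, g, m, p, rng)
        np.testing.assert_allclose(seeds.p1, [0.5, 0.5])  # S + (G - M)
        np.testing.assert_allclose(seeds.p2, [0.5, 0.5])  # G + (S - M)
        np.testing.assert_allclose(seeds.p3, [0.0, 0.0])  # M + (S - G) clipped

    def test_p4_perturbs_some_coordinates_upward(self, rng):
        p = CGOParams(dim=6, population_size=5, lower_bound=-100, upper_bound=100)
        s = np.zeros(6)
        seeds = generate_seeds(s, np.ones(6), np.full(6, 0.5), p, rng)
        delta = seeds.p4 - s
        changed = delta != 0
        assert 1 <= changed.sum() <= 6
        assert np.all(delta[changed] > 0) and np.all(delta[changed] < 1)

    def test_mismatched_lengths_rejected(self, rng):
        p = CGOParams(dim=3, population_size=5)
        with pytest.raises(ValueError):
            generate_seeds(np.zeros(3), np.zeros(2), np.zeros(3), p, rng)


class TestBounds:
    def test_clipping(self):
        p = CGOParams(dim=2, population_size=5)
        np.testing.assert_allclose(
            handle_bounds(np.array([1.5, -0.2]), p), [1.0, 0.0]
        )

    @given(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=4, max_size=4)
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_feasible(self, xs):
        p = CGOParams(dim=4, population_size=5)
        once = handle_bounds(np.array(xs), p)
        assert np.all(once >= 0.0) and np.all(once <= 1.0)
        np.testing.assert_array_equal(handle_bounds(once, p), once)


class TestReplacement:
    def _pop(self):
        pos = np.array([[0.1, 0.1], [0.2, 0.2], [0.3, 0.3]])
        fit = np.array([1.0, 2.0, 3.0])
        return SeedPopulation(pos, fit, pos[0].copy(), 1.0)

    def test_all_worse_leaves_population_unchanged(self):
        pop = self._pop()
        out = replace_if_better(pop, [(np.array([9.0, 9.0]), 50.0)])
        np.testing.assert_array_equal(out.positions, pop.positions)
        assert out.global_best_fitness == 1.0

    def test_better_candidate_becomes_global_best(self):
        pop = self._pop()
        cand = np.array([0.5, 0.5])
        out = replace_if_better(pop, [(cand, 0.25)])
        assert out.global_best_fitness == 0.25
        np.testing.assert_array_equal(out.global_best, cand)

    def test_cardinality_conserved_under_ties(self):
        pop = self._pop()
        # candidate ties the worst incumbent at the cut: incumbent wins
        out = replace_if_better(pop, [(np.array([7.0, 7.0]), 3.0)])
        assert out.size == 3
        np.testing.assert_array_equal(out.positions, pop.positions)
        # strictly better candidate does displace the worst incumbent
        out2 = replace_if_better(pop, [(np.array([8.0, 8.0]), 2.5)])
        assert out2.size == 3
        assert sorted(out2.fitness) == [1.0, 2.0, 2.5]


class TestOptimize:
    def test_single_iteration_evaluation_accounting(self):
        calls = {"n": 0}

        def obj(x):
            calls["n"] += 1
            return float(np.sum(x**2))

        p = CGOParams(dim=2, population_size=7, max_iterations=1, rng_seed=0)
        _, trace = optimize(obj, p)
        assert len(trace.best_fitness_per_iteration) == 1
        assert calls["n"] == 7 + 7 * 4
        assert trace.evaluations_used == calls["n"]

    def test_constant_objective_flat_trace(self):
        p = CGOParams(dim=3, population_size=5, max_iterations=10, rng_seed=2)
        _, trace = optimize(lambda x: 4.2, p)
        np.testing.assert_array_equal(trace.best_fitness_per_iteration, 4.2)

    def test_trace_nonincreasing_and_feasible(self):
        p = CGOParams(
            dim=4, population_size=8, max_iterations=30,
            lower_bound=-2, upper_bound=2, rng_seed=5,
        )
        pop, trace = optimize(lambda x: float(np.sum((x - 0.5) ** 2)), p)
        assert np.all(np.diff(trace.best_fitness_per_iteration) <= 0)
        assert np.all(pop.positions >= -2) and np.all(pop.positions <= 2)

    def test_bitwise_reproducibility(self):
        p = CGOParams(dim=3, population_size=6, max_iterations=15, rng_seed=9)
        obj = lambda x: float(np.sum(np.abs(x - 0.3)))
        _, t1 = optimize(obj, p)
        _, t2 = optimize(obj, p)
        np.testing.assert_array_equal(
            t1.best_fitness_per_iteration, t2.best_fitness_per_iteration
        )
        np.testing.assert_array_equal(t1.final_best_position, t2.final_best_position)

    def test_zero_volume_box_returns_single_point(self):
        p = CGOParams(
            dim=2, population_size=4, max_iterations=5,
            lower_bound=0.7, upper_bound=0.7, rng_seed=0,
        )
        pop, trace = optimize(lambda x: float(np.sum(x**2)), p)
        np.testing.assert_allclose(pop.global_best, [0.7, 0.7])
        np.testing.assert_allclose(
            trace.best_fitness_per_iteration, 2 * 0.7**2
        )

    def test_nonfinite_objective_reported_with_position(self):
        p = CGOParams(dim=2, population_size=4, max_iterations=2, rng_seed=0)
        with pytest.raises(ValueError, match="non-finite"):
            optimize(lambda x: float("nan"), p)

    def test_random_search_same_contract(self):
        p = CGOParams(dim=2, population_size=5, max_iterations=10, rng_seed=1)
        pop, trace = random_search(lambda x: float(np.sum(x**2)), p)
        assert np.all(np.diff(trace.best_fitness_per_iteration) <= 0)
        assert trace.evaluations_used == 5 + 10 * 20


class TestSierpinski:
    VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])

    @staticmethod
    def _inside(points, v, tol=1e-12):
        # barycentric coordinates all nonnegative
        t = np.linalg.inv(
            np.column_stack([v[0] - v[2], v[1] - v[2]])
        ) @ (points - v[2]).T
        bary = np.vstack([t, 1 - t.sum(axis=0)])
        return np.all(bary >= -tol)

    def test_points_inside_triangle(self):
        pts = chaos_game_sierpinski(
            self.VERTICES, 5000, np.random.default_rng(0)
        )
        assert pts.shape == (5000, 2)
        assert self._inside(pts, self.VERTICES)

    def test_collinear_vertices_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            chaos_game_sierpinski(
                np.array([[0, 0], [1, 1], [2, 2]]), 10, np.random.default_rng(0)
            )

    def test_repeated_vertex_choice_converges_to_that_vertex(self):
        rng = ScriptedRNG()
        rng.integers = lambda *a, **k: np.zeros(k.get("size", a[-1]), dtype=int)
        pts = chaos_game_sierpinski(self.VERTICES, 50, rng)
        # after 20 burn-in halvings toward vertex 0 the point is pinned there
        assert np.abs(pts - self.VERTICES[0]).max() < 1e-5

    def test_box_counting_oracle_on_known_sets(self, rng):
        square = rng.random((20000, 2))
        assert 1.85 < box_counting_dimension(square) < 2.05
        line = np.column_stack([np.linspace(0, 1, 20000), np.zeros(20000)])
        assert 0.8 < box_counting_dimension(line) < 1.1
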