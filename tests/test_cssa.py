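"""Chaotic sparrow search: role updates, chaotic refinement, optimization."""

import math

import numpy as np
import pytest

from histotex.cssa import (BENCHMARKS, CSSAConfig, Dimension,
                           SparrowPopulation, chaotic_candidate,
                           fitness_error_rate, logistic_map_sequence,
                           optimize, random_search, rastrigin, rosenbrock,
                           sphere, tune_hyperparameters, update_discoverers,
                           update_joiners, update_vigilantes)


def box(dim, lo=-5.0, hi=5.0):
    return np.tile([lo, hi], (dim, 1))


class StubRng:
    """Scripted stand-in for a Generator: pops queued uniform/normal draws."""

    def __init__(self, uniforms=(), normals=()):
        self.uniforms = list(uniforms)
        self.normals = list(normals)

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is None:
            return low + (high - low) * self.uniforms.pop(0)
        return np.array([low + (high - low) * self.uniforms.pop(0)
                         for _ in range(int(np.prod(size)))]).reshape(size)

    def normal(self, loc=0.0, scale=1.0, size=None):
        if size is None:
            return loc + scale * self.normals.pop(0)
        return np.array([loc + scale * self.normals.pop(0)
                         for _ in range(int(np.prod(size)))]).reshape(size)

    def choice(self, n, size=None, replace=True):
        return np.arange(size)


class TestLogisticMap:
    def test_first_iterates_from_0_3(self):
        seq = logistic_map_sequence(0.3, 3)
        np.testing.assert_allclose(seq, [0.3, 0.84, 0.5376], atol=1e-15)

    @pytest.mark.parametrize("bad", [0.25, 0.5, 0.75, 1.0, 0.0, -0.1, 1.3])
    def test_fixed_point_and_out_of_range_seeds_rejected(self, bad):
        with pytest.raises(ValueError):
            logistic_map_sequence(bad, 5)

    def test_iterates_stay_in_unit_interval(self):
        seq = logistic_map_sequence(0.123, 10_000)
        assert np.all((seq >= 0.0) & (seq <= 1.0))


class TestChaoticCandidate:
    def test_first_iteration_is_pure_chaotic_point(self):
        cfg = CSSAConfig(bounds=box(3, 0.0, 2.0), N=4, T=10)
        cl = chaotic_candidate(np.array([1.5, 1.5, 1.5]), 0.25, 1, cfg)
        np.testing.assert_allclose(cl, 0.0 + 0.25 * 2.0)

    def test_worked_scalar_example(self):
        # a=0, b=1, rho=0.3, TP=0.9, t=T=2: SC=0.5, P=0.3, CL=0.6
        cfg = CSSAConfig(bounds=box(1, 0.0, 1.0), N=4, T=2)
        cl = chaotic_candidate(np.array([0.9]), 0.3, 2, cfg)
        assert cl[0] == pytest.approx(0.6, abs=1e-15)

    def test_late_iterations_stay_near_best_for_large_t(self):
        cfg = CSSAConfig(bounds=box(2, -1.0, 1.0), N=4, T=1000)
        best = np.array([0.4, -0.2])
        cl = chaotic_candidate(best, 0.9, 1000, cfg)
        np.testing.assert_allclose(cl, best, atol=2e-3)

    def test_convex_combination_stays_in_bounds(self, rng):
        cfg = CSSAConfig(bounds=box(4, -3.0, 7.0), N=4, T=20)
        for t in range(1, 21):
            best = rng.uniform(-3.0, 7.0, size=4)
            cl = chaotic_candidate(best, rng.uniform(), t, cfg)
            assert np.all(cl >= -3.0) and np.all(cl <= 7.0)


class TestRoleUpdates:
    def _pop(self, X, fitness):
        X = np.asarray(X, dtype=float)
        f = np.asarray(fitness, dtype=float)
        pop = SparrowPopulation(X=X.copy(), fitness=f.copy(),
                                x_best=X[0].copy(), f_g=0.0,
                                x_worst=X[0].copy(), f_w=0.0)
        pop.refresh_extremes()
        return pop

    def test_discoverer_safe_branch_scalar_example(self):
        # alpha = 1, T = 10, rank i = 1: x *= exp(-1/10)
        cfg = CSSAConfig(bounds=box(3, -5, 5), N=4, T=10, ST=0.8, pd_frac=0.25)
        pop = self._pop(np.ones((4, 3)), [1.0, 2.0, 3.0, 4.0])
        rng = StubRng(uniforms=[0.1, 0.0])   # R2=0.1 < ST; alpha = 1-0 = 1
        update_discoverers(pop, cfg, rng, iteration=1)
        np.testing.assert_allclose(pop.X[0], math.exp(-0.1), atol=1e-15)
        np.testing.assert_array_equal(pop.X[1:], np.ones((3, 3)))

    def test_discoverer_alarm_branch_zero_step_is_identity(self):
        cfg = CSSAConfig(bounds=box(2, -5, 5), N=4, T=10, ST=0.5, pd_frac=0.25)
        pop = self._pop(np.full((4, 2), 2.0), [1.0, 2.0, 3.0, 4.0])
        rng = StubRng(uniforms=[0.9], normals=[0.0])  # R2 >= ST, Q = 0
        update_discoverers(pop, cfg, rng, iteration=1)
        np.testing.assert_array_equal(pop.X[0], [2.0, 2.0])

    def test_discoverer_clipping_lands_on_bound(self):
        cfg = CSSAConfig(bounds=box(2, 1.0, 5.0), N=4, T=10, ST=0.8,
                         pd_frac=0.25)
        pop = self._pop(np.full((4, 2), 1.2), [1.0, 2.0, 3.0, 4.0])
        rng = StubRng(uniforms=[0.0, 0.99])   # tiny alpha, huge shrink
        update_discoverers(pop, cfg, rng, iteration=1)
        np.testing.assert_array_equal(pop.X[0], [1.0, 1.0])

    def test_joiner_far_half_with_zero_q_goes_to_origin(self):
        cfg = CSSAConfig(bounds=box(2, -5, 5), N=4, T=10, pd_frac=0.25)
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        pop = self._pop(X, [1.0, 2.0, 3.0, 4.0])
        rng = StubRng(uniforms=[0.5] * 8, normals=[0.0, 0.0])
        update_joiners(pop, cfg, rng)
        # joiners ranked 3 and 4 (> N/2 = 2) collapse to Q * exp(...) = 0
        np.testing.assert_array_equal(pop.X[2], [0.0, 0.0])
        np.testing.assert_array_equal(pop.X[3], [0.0, 0.0])

    def test_joiner_near_best_at_best_is_fixed_point(self):
        cfg = CSSAConfig(bounds=box(2, -5, 5), N=8, T=10, pd_frac=0.125)
        X = np.tile([1.5, -0.5], (8, 1))
        pop = self._pop(X, np.arange(8.0))
        rng = StubRng(uniforms=[0.3] * 50, normals=[0.7] * 10)
        update_joiners(pop, cfg, rng)
        # rank-2 joiner sits exactly at x_best: |x - x_best| = 0 everywhere
        np.testing.assert_array_equal(pop.X[1], [1.5, -0.5])

    def test_joiner_at_worst_moves_to_q(self):
        cfg = CSSAConfig(bounds=box(2, -5, 5), N=4, T=10, pd_frac=0.25)
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        pop = self._pop(X, [1.0, 2.0, 3.0, 4.0])
        rng = StubRng(uniforms=[0.5] * 8, normals=[0.0, 1.7])
        update_joiners(pop, cfg, rng)
        # the worst sparrow: exponent (x_worst - x)/i^2 = 0, position = Q * 1
        np.testing.assert_allclose(pop.X[3], [1.7, 1.7])

    def test_vigilante_edge_with_zero_beta_lands_on_worst(self):
        cfg = CSSAConfig(bounds=box(2, -5, 5), N=4, T=10, sd_frac=0.25)
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        # sparrow 1 is not at the best fitness: edge branch, beta = 0
        pop2 = self._pop(X, [1.0, 2.0, 3.0, 4.0])

        class Pick1(StubRng):
            def choice(self, n, size=None, replace=True):
                return np.array([1])

        update_vigilantes(pop2, cfg, Pick1(normals=[0.0]))
        np.testing.assert_array_equal(pop2.X[1], pop2.x_worst)

    def test_vigilante_center_at_worst_position_is_fixed_point(self):
        cfg = CSSAConfig(bounds=box(2, -5, 5), N=4, T=10, sd_frac=0.25)
        X = np.array([[3.0, 3.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        pop = self._pop(X, [1.0, 2.0, 3.0, 4.0])
        # best sparrow 0 sits exactly at x_worst: |x - x_worst| = 0
        rng = StubRng(uniforms=[0.9])
        update_vigilantes(pop, cfg, rng)
        np.testing.assert_array_equal(pop.X[0], [3.0, 3.0])

    def test_vigilante_guard_path_step_is_v_over_e(self):
        # f_i = f_g = f_w, K = 1: step = |x - x_worst| / e exactly
        e = 0.5
        cfg = CSSAConfig(bounds=box(1, -100.0, 100.0), N=4, T=10,
                         sd_frac=0.25, e=e)
        X = np.array([[1.0], [1.0], [1.0], [3.0]])
        pop = self._pop(X, [2.0, 2.0, 2.0, 2.0])
        pop.x_worst = np.array([3.0])

        class PickK(StubRng):
            def choice(self, n, size=None, replace=True):
                return np.array([0])

        update_vigilantes(pop, cfg, PickK(uniforms=[1.0]))
        # v = |1 - 3| = 2, denominator = (2-2) + e: step = 2/0.5 = 4
        np.testing.assert_allclose(pop.X[0], [5.0])


class TestFitnessErrorRate:
    def test_direct_percentages(self):
        truth = np.arange(100) % 4
        pred = truth.copy()
        pred[:10] = (pred[:10] + 1) % 4
        assert fitness_error_rate(pred, truth) == pytest.approx(10.0)
        assert fitness_error_rate(truth, truth) == 0.0
        assert fitness_error_rate((truth + 1) % 4, truth) == 100.0

    def test_empty_vectors_rejected(self):
        with pytest.raises(ValueError):
            fitness_error_rate([], [])


class TestOptimize:
    def test_sphere_converges_and_beats_uniform_sampling(self):
        cfg = CSSAConfig(bounds=box(5), N=20, T=100, seed=11)
        res = optimize(sphere, cfg)
        assert res.f_best < 1e-2
        rng = np.random.default_rng(999)
        uniform_best = min(sphere(rng.uniform(-5, 5, size=5))
                           for _ in range(2000))
        assert res.f_best < uniform_best

    def test_single_iteration_history_and_elitism(self):
        cfg = CSSAConfig(bounds=box(3), N=6, T=1, seed=2)
        res = optimize(sphere, cfg)
        assert len(res.history) == 1
        assert res.f_best <= res.f_initial

    def test_same_seed_identical_history(self):
        cfg = CSSAConfig(bounds=box(4), N=10, T=25, seed=5)
        a = optimize(rosenbrock, cfg)
        b = optimize(rosenbrock, cfg)
        np.testing.assert_array_equal(a.history, b.history)

    @pytest.mark.parametrize("fn", [sphere, rosenbrock, rastrigin])
    def test_history_non_increasing_across_seeds(self, fn):
        for seed in range(20):
            cfg = CSSAConfig(bounds=box(3), N=8, T=30, seed=seed)
            res = optimize(fn, cfg)
            assert np.all(np.diff(res.history) <= 0.0)
            assert res.f_best == res.history[-1]

    def test_all_evaluated_positions_stay_in_bounds(self):
        lo, hi = -2.0, 3.0

        def guarded(x):
            assert np.all(x >= lo - 1e-12) and np.all(x <= hi + 1e-12)
            return sphere(x)

        cfg = CSSAConfig(bounds=box(4, lo, hi), N=8, T=20, seed=3)
        optimize(guarded, cfg)

    def test_beats_random_search_at_equal_budget(self):
        wins = []
        for seed in range(20):
            cfg = CSSAConfig(bounds=box(5), N=20, T=50, seed=seed)
            res = optimize(sphere, cfg)
            base = random_search(sphere, box(5), res.n_evaluations, seed=seed)
            wins.append(res.f_best < base.f_best)
        assert np.median([float(w) for w in wins]) == 1.0

    def test_objective_exception_carries_iteration_context(self):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] > 10:
                raise RuntimeError("boom")
            return sphere(x)

        cfg = CSSAConfig(bounds=box(2), N=8, T=5, seed=0)
        with pytest.raises(RuntimeError):
            optimize(flaky, cfg)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [dict(N=3), dict(T=0), dict(ST=0.4),
                                    dict(ST=1.1), dict(e=0.0), dict(mu=3.9),
                                    dict(rho1=0.75)])
    def test_invalid_settings_rejected(self, kw):
        with pytest.raises(ValueError):
            CSSAConfig(bounds=box(2), **kw)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            CSSAConfig(bounds=np.array([[1.0, 1.0]]))


class TestTuneHyperparameters:
    def test_recovers_quadratic_optimum_within_ten_percent(self):
        space = [Dimension("lr", 1e-3, 1e-1, "log")]
        best, _ = tune_hyperparameters(
            space, lambda hp: (hp["lr"] - 0.01) ** 2,
            config_kwargs=dict(N=10, T=20), seed=4)
        assert abs(best["lr"] - 0.01) <= 0.1 * 0.01

    def test_integer_dimension_decodes_to_range(self):
        space = [Dimension("hidden", 4, 64, "integer")]
        seen = []
        best, _ = tune_hyperparameters(
            space, lambda hp: seen.append(hp["hidden"]) or float(hp["hidden"]),
            config_kwargs=dict(N=6, T=5), seed=1)
        assert all(isinstance(v, int) and 4 <= v <= 64 for v in seen)
        assert best["hidden"] == 4

    def test_degenerate_space_returns_the_constant(self):
        space = [Dimension("c", 2.5, 2.5, "continuous")]
        best, _ = tune_hyperparameters(space, lambda hp: hp["c"] ** 2,
                                       config_kwargs=dict(N=4, T=2), seed=0)
        assert best["c"] == pytest.approx(2.5, abs=1e-6)

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters([], lambda hp: 0.0)

    def test_warm_start_never_worse_than_the_seeded_point(self):
        space = [Dimension("lr", 1e-3, 1e-1, "log"),
                 Dimension("width", 4, 32, "integer")]

        def objective(hp):
            return (math.log10(hp["lr"]) + 2.3) ** 2 + (hp["width"] - 17) ** 2

        warm = {"lr": 0.01, "width": 8}
        best, res = tune_hyperparameters(space, objective,
                                         config_kwargs=dict(N=6, T=4),
                                         seed=7, warm_start=warm)
        assert res.f_best <= objective(warm)

    def test_benchmark_registry_exposes_three_functions(self):
        assert set(BENCHMARKS) == {"sphere", "rosenbrock", "rastrigin"}
        assert BENCHMARKS["sphere"](np.zeros(4)) == 0.0
        assert rastrigin(np.zeros(3)) == 0.0
        assert rosenbrock(np.ones(3)) == 0.0
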