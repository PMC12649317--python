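"""Tests for the DE variants, the subpopulation-ranked DE, and PSO."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from quadtune.optimizers import (
    Individual,
    OptimizerConfig,
    Population,
    Strategy,
    clip_to_bounds,
    crossover_binomial,
    de_best_1,
    de_rand_to_best_1,
    inertia_weight,
    initialize_population,
    mutation_factors,
    run,
    run_de,
    run_pso,
    select_greedy,
    stage_partition,
)


def sphere(x):
    return float(np.sum(x * x))


def config(**kw):
    base = dict(D=2, lower=-5.0, upper=5.0, strategy=Strategy.DE_IMPROVED,
                N=20, G=25, seed=0)
    base.update(kw)
    return OptimizerConfig(**base)


class TestInitialization:
    def test_all_coordinates_within_bounds(self, rng):
        cfg = config(D=5, lower=0.0, upper=1.0)
        pop = initialize_population(cfg, rng, sphere)
        assert (pop.x >= 0).all() and (pop.x <= 1).all()
        assert np.isfinite(pop.fitness).all()

    def test_degenerate_interval_gives_constant(self, rng):
        cfg = config(D=3, lower=2.5, upper=2.5)
        pop = initialize_population(cfg, rng)
        assert (pop.x == 2.5).all()

    def test_draws_are_uniform(self):
        cfg = config(D=1, lower=-3.0, upper=7.0, N=10_000, G=1,
                     strategy=Strategy.DE_RAND_1)
        pop = initialize_population(cfg, np.random.default_rng(1))
        stat = kstest((pop.x[:, 0] + 3.0) / 10.0, "uniform")
        assert stat.pvalue > 0.01

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            config(lower=1.0, upper=-1.0)


class TestStagePartition:
    @staticmethod
    def _pop(n, rng):
        return Population(x=rng.random((n, 2)), fitness=rng.random(n))

    @pytest.mark.parametrize("g,expected", [(0, (4, 10, 6)), (10, (8, 8, 4)), (20, (12, 6, 2))])
    def test_stage_sizes_for_population_20(self, g, expected, rng):
        part = stage_partition(self._pop(20, rng), g, 25)
        assert part.sizes == expected

    @pytest.mark.parametrize("n", [10, 20, 50])
    @pytest.mark.parametrize("g", [0, 9, 12, 18, 24])
    def test_sizes_sum_to_population_and_disjoint(self, n, g, rng):
        part = stage_partition(self._pop(n, rng), g, 25)
        idx = np.concatenate([part.elite, part.middle, part.inferior])
        assert len(idx) == n and len(set(idx)) == n

    def test_elite_holds_best_ranked(self, rng):
        pop = self._pop(20, rng)
        part = stage_partition(pop, 0, 25)
        worst_elite = pop.fitness[part.elite].max()
        assert worst_elite <= pop.fitness[part.middle].min()
        assert pop.fitness[part.middle].max() <= pop.fitness[part.inferior].min()

    def test_stage_boundaries_are_real_valued(self, rng):
        # with G=25: g=8 is early (8 <= 25/3 is False -> middle?); check edges
        pop = self._pop(20, rng)
        assert stage_partition(pop, 8, 25).stage == "early"  # 8 <= 8.33
        assert stage_partition(pop, 9, 25).stage == "middle"
        assert stage_partition(pop, 16, 25).stage == "middle"  # 16 <= 16.67
        assert stage_partition(pop, 17, 25).stage == "late"

    def test_override_ratios_taken_literally(self, rng):
        part = stage_partition(self._pop(10, rng), 0, 25, ratio_override=(0, 10, 0))
        assert part.sizes == (0, 10, 0)


class TestMutation:
    def test_f1_vanishes_at_final_generation(self, rng):
        cfg = config()
        for _ in range(10):
            f1, _ = mutation_factors(cfg.G, cfg.G, cfg, rng)
            assert f1 == 0.0

    def test_f3_schedule_endpoints(self, rng):
        cfg = config()  # alpha2 = alpha3 = 0.3
        assert mutation_factors(0, cfg.G, cfg, rng)[1] == pytest.approx(0.6)
        assert mutation_factors(cfg.G, cfg.G, cfg, rng)[1] == pytest.approx(0.3)

    def test_zero_generations_rejected(self, rng):
        with pytest.raises(ValueError):
            mutation_factors(0, 0, config(), rng)

    def test_best_rule_collapses_with_zero_factor(self):
        best = np.array([1.0, 2.0])
        v = de_best_1(best, np.array([5.0, 5.0]), np.array([-1.0, 3.0]), 0.0)
        assert (v == best).all()

    def test_rand_to_best_collapses_with_zero_factors(self):
        xi = np.array([0.5, -0.5])
        v = de_rand_to_best_1(xi, np.ones(2), np.zeros(2), np.ones(2), 0.0, 0.0)
        assert (v == xi).all()

    def test_middle_subpopulation_rule_hand_value(self):
        # x_i + F2 (x_best - x_i) + F3 (x_r1 - x_r2)
        v = de_rand_to_best_1(
            np.zeros(2), np.ones(2), np.array([1.0, 0.0]), np.array([0.0, 1.0]),
            0.4, 0.5,
        )
        assert v == pytest.approx([0.9, -0.1])


class TestCrossover:
    def test_cr_one_takes_whole_mutant(self, rng):
        t, m = np.zeros(8), np.ones(8)
        assert (crossover_binomial(t, m, 1.0, rng) == m).all()

    def test_cr_zero_takes_exactly_one_mutant_coordinate(self, rng):
        t, m = np.zeros(8), np.ones(8)
        for _ in range(50):
            u = crossover_binomial(t, m, 0.0, rng)
            assert u.sum() == 1.0

    def test_mean_mutant_fraction_matches_closed_form(self):
        # E[fraction from mutant] = CR + (1 - CR)/D
        rng = np.random.default_rng(3)
        cr, d, reps = 0.75, 10, 20_000
        t, m = np.zeros(d), np.ones(d)
        fracs = np.array([crossover_binomial(t, m, cr, rng).mean() for _ in range(reps)])
        expected = cr + (1 - cr) / d
        se = fracs.std(ddof=1) / math.sqrt(reps)
        assert abs(fracs.mean() - expected) <= 3 * se

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            crossover_binomial(np.zeros(3), np.zeros(4), 0.5, rng)


class TestClipAndSelect:
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_clip_is_idempotent_and_in_bounds(self, values):
        v = np.array(values)
        lo, hi = np.full(len(v), -3.0), np.full(len(v), 3.0)
        c = clip_to_bounds(v, lo, hi)
        assert (c >= lo).all() and (c <= hi).all()
        assert (clip_to_bounds(c, lo, hi) == c).all()
        assert (c[(v >= lo) & (v <= hi)] == v[(v >= lo) & (v <= hi)]).all()

    def test_clip_hits_the_violated_boundary(self):
        lo, hi = np.array([0.0]), np.array([1.0])
        assert clip_to_bounds(np.array([6.0]), lo, hi)[0] == 1.0
        assert clip_to_bounds(np.array([-5.0]), lo, hi)[0] == 0.0

    def test_greedy_selection_rules(self):
        x = Individual(np.zeros(1), 2.0)
        u = Individual(np.ones(1), 1.0)
        assert select_greedy(x, u) is u
        assert select_greedy(u, x) is u  # target better, keeps target
        tie = Individual(np.ones(1), 2.0)
        assert select_greedy(x, tie) is x  # ties keep the target

    def test_non_finite_fitness_handling(self):
        good = Individual(np.zeros(1), 1.0)
        bad = Individual(np.ones(1), math.inf)
        assert select_greedy(good, bad) is good
        assert select_greedy(bad, good) is good
        with pytest.raises(ValueError):
            select_greedy(bad, Individual(np.ones(1), math.nan))


@pytest.mark.parametrize("strategy", [
    Strategy.DE_RAND_1, Strategy.DE_BEST_1, Strategy.DE_RAND_TO_BEST_1,
    Strategy.DE_IMPROVED, Strategy.PSO,
])
class TestRunContracts:
    def test_curve_monotone_and_population_invariants(self, strategy):
        cfg = config(strategy=strategy, D=3, G=15, seed=3)
        sizes, bound_ok = [], []

        def cb(g, x, f):
            sizes.append(len(x))
            bound_ok.append(((x >= cfg.lower) & (x <= cfg.upper)).all())

        res = run(sphere, cfg, callback=cb)
        assert set(sizes) == {cfg.N}
        assert all(bound_ok)
        assert (np.diff(res.convergence) <= 0).all()
        assert res.convergence[-1] == res.best_fitness
        assert len(res.convergence) == cfg.G + 1
        assert res.evaluations == cfg.N * (cfg.G + 1)

    def test_fixed_seed_is_reproducible(self, strategy):
        cfg = config(strategy=strategy, seed=9)
        a, b = run(sphere, cfg), run(sphere, cfg)
        assert (a.best_x == b.best_x).all() and a.best_fitness == b.best_fitness
        assert (a.convergence == b.convergence).all()

    def test_one_dimensional_quadratic_matches_grid_oracle(self, strategy):
        # brute-force oracle: dense grid at resolution 1e-4
        grid = np.arange(-1.0, 1.0 + 1e-4, 1e-4)
        f = lambda x: float((x[0] - 0.3) ** 2)  # noqa: E731
        oracle = min(f([g]) for g in grid)
        cfg = config(strategy=strategy, D=1, lower=-1.0, upper=1.0, N=20, G=25, seed=2)
        res = run(f, cfg)
        assert res.best_fitness <= oracle + 1e-3

    def test_objective_failure_reports_generation(self, strategy):
        def broken(x):
            raise RuntimeError("sensor offline")

        with pytest.raises(RuntimeError, match="generation 0"):
            run(broken, config(strategy=strategy))


class TestConvergence:
    def test_de_variants_solve_sphere(self):
        for strategy in (Strategy.DE_RAND_1, Strategy.DE_BEST_1,
                         Strategy.DE_RAND_TO_BEST_1, Strategy.DE_IMPROVED):
            hits = sum(
                run(sphere, config(strategy=strategy, D=2, G=50, seed=s)).best_fitness < 1e-2
                for s in range(50)
            )
            assert hits >= 47, strategy

    def test_pso_solves_sphere(self):
        hits = sum(
            run(sphere, config(strategy=Strategy.PSO, D=2, G=50, seed=s)).best_fitness < 1e-2
            for s in range(50)
        )
        assert hits >= 45


class TestPSO:
    def test_inertia_weight_schedule(self):
        assert inertia_weight(0, 25) == pytest.approx(0.9)
        assert inertia_weight(25, 25) == pytest.approx(0.4)
        assert inertia_weight(12.5, 25) == pytest.approx(0.65)

    def test_swarm_at_gbest_with_zero_velocity_is_stationary(self):
        # all particles on the optimum: no force term is nonzero
        cfg = config(strategy=Strategy.PSO, D=2, lower=0.7, upper=0.7, G=10)
        traj = []
        run_pso(sphere, cfg, callback=lambda g, x, f: traj.append(x.copy()))
        assert all((x == traj[0]).all() for x in traj)


class TestImprovedReduction:
    def test_collapsed_improved_de_equals_rand_to_best(self):
        """With ratios 0:10:0, alpha3 = 0, alpha2 = F, F2 = lambda, the
        improved algorithm must reproduce DE/rand-to-best/1/bin bit-for-bit
        on a shared draw sequence."""
        base = dict(D=4, lower=-3.0, upper=3.0, N=10, G=12, F=0.45,
                    CR=0.75, lambda_rtb=0.3, seed=1)
        classic = OptimizerConfig(strategy=Strategy.DE_RAND_TO_BEST_1, **base)
        collapsed = OptimizerConfig(
            strategy=Strategy.DE_IMPROVED, stage_ratio_override=(0, 10, 0),
            alpha3=0.0, alpha2=0.45, F2=0.3, **base,
        )
        hist_a, hist_b = [], []
        run_de(sphere, classic, np.random.default_rng(7),
               callback=lambda g, x, f: hist_a.append((x, f)))
        run_de(sphere, collapsed, np.random.default_rng(7),
               callback=lambda g, x, f: hist_b.append((x, f)))
        assert len(hist_a) == len(hist_b)
        for (xa, fa), (xb, fb) in zip(hist_a, hist_b):
            assert (xa == xb).all()
            assert (fa == fb).all()

    def test_improved_requires_minimum_population(self):
        with pytest.raises(ValueError):
            config(N=4)


class TestConfigValidation:
    def test_strategy_coercion_from_string(self):
        cfg = config(strategy="DE-i")
        assert cfg.strategy is Strategy.DE_IMPROVED

    def test_cr_range_checked(self):
        with pytest.raises(ValueError):
            config(CR=1.5)

    def test_pso_strategy_rejected_by_run_de(self):
        with pytest.raises(ValueError):
            run_de(sphere, config(strategy=Strategy.PSO))
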