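"""Genetic algorithm: constraints, repair, cloning, mutation, evolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import plsched as P
from plsched.ga import (GAConfig, MIN_GAP, Schedule, T_MAX, WINDOW,
                        clone_indices, evaluate, init_population,
                        max_feasible_ns, mutate, random_schedule, repair,
                        validate_times)
from plsched.model import scenario


def assert_valid(times):
    validate_times(np.asarray(times))   # raises on violation


class TestCloneIndices:
    def test_weighting_of_top_ranks(self):
        src = [clone_indices(j) for j in range(1, 101)]
        assert src[:14] == [1] * 14          # 14 clones of the best
        assert src[14:19] == [2] * 5         # 5 of the second best
        assert src[19:24] == [3] * 5         # 5 of the third
        assert src[-1] == 52                 # last clone sources rank 52

    def test_monotone_and_total(self):
        src = [clone_indices(j) for j in range(1, 101)]
        assert all(a <= b for a, b in zip(src, src[1:]))
        assert src[0] == 1 and len(src) == 100

    def test_other_population_sizes_rejected(self):
        with pytest.raises(NotImplementedError):
            clone_indices(1, n_organisms=50)


class TestRepair:
    def test_valid_schedule_unchanged(self):
        t = np.array([0.0, 10.0, 70.0, 200.0])
        assert np.array_equal(repair(t), t)

    def test_window_violation_moves_to_nearest_valid(self):
        # 62 is nearer to 60 (valid) than to 65+; unconstrained -> 60
        out = repair(np.array([0.0, 62.0, 200.0]))
        assert out[1] == 60.0
        # 64 is nearer to the upper edge
        out = repair(np.array([0.0, 64.0, 200.0]))
        assert out[1] > WINDOW[1]
        assert_valid(out)

    def test_window_with_gap_pressure_goes_past_the_window(self):
        # previous sample at 58 rules out t = 60 (gap <= 5)
        out = repair(np.array([0.0, 58.0, 62.0, 200.0]))
        assert out[2] > WINDOW[1]
        assert_valid(out)

    def test_gap_violation_pushed_forward(self):
        out = repair(np.array([0.0, 100.0, 103.0]))
        assert out[2] > 105.0
        assert out[2] - out[1] > MIN_GAP
        assert_valid(out)

    def test_overrun_packs_back_from_the_end(self):
        out = repair(np.array([0.0, 597.0, 599.0]))
        assert out[-1] == T_MAX
        assert_valid(out)

    def test_clamps_out_of_horizon_times(self):
        out = repair(np.array([0.0, -30.0, 650.0, 100.0]))
        assert_valid(out)
        assert out.min() == 0.0 and out.max() <= T_MAX

    def test_unrepairable_raises(self):
        with pytest.raises(ValueError):
            repair(np.linspace(0, 600, 130))

    @given(st.lists(st.floats(min_value=-50, max_value=650,
                              allow_nan=False), min_size=2, max_size=20))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_repair_always_valid_or_raises(self, raw):
        raw = [0.0] + raw
        try:
            out = repair(np.array(raw))
        except ValueError:
            return
        assert_valid(out)

    def test_repair_idempotent(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            out = repair(np.concatenate([[0.0], rng.uniform(0, 600, 9)]))
            assert np.array_equal(repair(out), out)


class TestSchedule:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Schedule(np.array([1.0, 10.0]))       # must start at 0
        with pytest.raises(ValueError):
            Schedule(np.array([0.0, 4.0]))        # gap too small
        with pytest.raises(ValueError):
            Schedule(np.array([0.0, 63.0]))       # inside the window
        s = Schedule(np.array([0.0, 60.0, 100.0]))
        assert s.n_s == 3

    def test_max_feasible(self):
        assert max_feasible_ns() == 119


class TestPopulation:
    def test_init_deterministic_and_valid(self):
        cfg = GAConfig(scenarios=(scenario(1, 1),), n_s=8, seed=13,
                       n_generations=1)
        pop_a = init_population(cfg)
        pop_b = init_population(cfg)
        assert len(pop_a) == 100
        for a, b in zip(pop_a, pop_b):
            assert np.array_equal(a, b)
            assert_valid(a)
            assert a[0] == 0.0

    def test_infeasible_ns_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(scenarios=(scenario(1, 1),), n_s=120)


class TestMutate:
    def test_zero_sigma_identity(self):
        pop = [random_schedule(6, np.random.default_rng(k)) for k in range(5)]
        out = mutate(pop, 0.0, seed=0, generation=1)
        for a, b in zip(pop, out):
            assert np.array_equal(a, b)

    def test_elite_untouched_everyone_valid(self):
        pop = [random_schedule(10, np.random.default_rng(k))
               for k in range(20)]
        for g in range(5):
            out = mutate(pop, 16.0, seed=3, generation=g)
            assert np.array_equal(out[0], pop[0])
            for t in out:
                assert_valid(t)
            pop = out

    def test_mutation_reproducible(self):
        pop = [random_schedule(6, np.random.default_rng(k)) for k in range(4)]
        a = mutate(pop, 16.0, seed=1, generation=2)
        b = mutate(pop, 16.0, seed=1, generation=2)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)


class TestEvaluate:
    def test_single_scenario_worst_case_degenerates(self):
        cfg = GAConfig(scenarios=(scenario(1, 1),), n_s=6, seed=2,
                       n_generations=1)
        pop = init_population(cfg)[:10]
        rec = evaluate(pop, cfg)
        assert np.array_equal(rec.worst_case_metrics,
                              rec.per_scenario_metrics[:, 0])
        assert np.all(np.diff(rec.worst_case_metrics) >= 0)

    def test_worst_case_is_max_over_scenarios(self):
        cfg = GAConfig(scenarios=(scenario(1, 1), scenario(1, 3)), n_s=6,
                       seed=2, n_generations=1)
        pop = init_population(cfg)[:8]
        rec = evaluate(pop, cfg)
        assert np.allclose(rec.worst_case_metrics,
                           rec.per_scenario_metrics.max(axis=1))


class TestRun:
    def test_single_generation(self):
        cfg = GAConfig(scenarios=(scenario(1, 1),), n_s=5, n_generations=1,
                       seed=7)
        res = P.run(cfg)
        assert len(res.history) == 1
        rec = evaluate(init_population(cfg), cfg)
        assert res.best_metric == rec.best_metric

    def test_reproducible_histories(self):
        cfg = GAConfig(scenarios=(scenario(1, 1),), n_s=6, n_generations=5,
                       seed=21)
        a, b = P.run(cfg), P.run(cfg)
        assert np.array_equal(a.best_metric_trace, b.best_metric_trace)
        assert np.array_equal(a.best_schedule, b.best_schedule)

    def test_improves_on_initial_population(self):
        cfg = GAConfig(scenarios=(scenario(1, 1),), n_s=8, n_generations=12,
                       seed=5)
        res = P.run(cfg)
        trace = res.best_metric_trace
        assert np.all(np.diff(trace) <= 0)          # elitism, exactly
        assert trace[-1] < trace[0]                 # actually improved
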