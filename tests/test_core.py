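"""Unit and property tests for the HGS engine primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhgs import (HGSParams, RandomStream, SearchSpace, clamp_to_bounds,
                  initialize_population, make_benchmark, optimize)
from mhgs.core import (hunger_increment, hunger_weights, position_update,
                       shrink_factor, variation_control)


class TestSearchSpace:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="lower bound exceeds"):
            SearchSpace(3, lower=[0, 5, 0], upper=[1, 2, 1])

    def test_dim_must_be_positive(self):
        with pytest.raises(ValueError):
            SearchSpace(0, -1, 1)


class TestInitialization:
    def test_shape_and_bounds(self, rng):
        space = SearchSpace(10, -100, 100)
        pop = initialize_population(space, HGSParams(n_agents=30), rng)
        assert pop.positions.shape == (30, 10)
        assert np.all(pop.positions >= -100) and np.all(pop.positions <= 100)
        assert np.all(pop.hunger == 0)
        assert np.all(np.isnan(pop.fitness))
        assert pop.fe == 0

    def test_degenerate_bounds_collapse_to_point(self, rng):
        space = SearchSpace(4, 3.5, 3.5)
        pop = initialize_population(space, HGSParams(n_agents=5), rng)
        assert np.all(pop.positions == 3.5)

    def test_same_seed_bit_identical(self):
        space = SearchSpace(6, -5, 5)
        a = initialize_population(space, HGSParams(), RandomStream(7))
        b = initialize_population(space, HGSParams(), RandomStream(7))
        np.testing.assert_array_equal(a.positions, b.positions)


class TestVariationControl:
    def test_zero_gap_gives_one(self):
        assert variation_control(5.0, 5.0) == 1.0

    def test_unit_gap_closed_form(self):
        expected = 2.0 / (math.e + 1.0 / math.e)
        assert variation_control(6.0, 5.0) == pytest.approx(expected, abs=1e-12)

    def test_large_gap_tiny_and_monotone(self):
        v20 = variation_control(20.0, 0.0)
        assert v20 == pytest.approx(2.0 / (math.exp(20) + math.exp(-20)),
                                    rel=1e-12)
        gaps = [0.0, 0.5, 1.0, 5.0, 20.0, 100.0]
        vals = [variation_control(g, 0.0) for g in gaps]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_huge_gap_does_not_overflow(self):
        assert variation_control(1e9, 0.0) == 0.0

    def test_nonfinite_fitness_rejected(self):
        with pytest.raises(ValueError):
            variation_control(np.nan, 0.0)

    @given(st.floats(-350, 350), st.floats(-350, 350))
    def test_range_invariant(self, f, bf):
        # |gap| <= 700 keeps sech above the double-precision underflow floor
        e = variation_control(f, bf)
        assert 0.0 < e <= 1.0


class TestShrinkFactor:
    @pytest.mark.parametrize("fe,max_fe,expected",
                             [(0, 45000, 2.0), (45000, 45000, 0.0),
                              (22500, 45000, 1.0)])
    def test_schedule(self, fe, max_fe, expected):
        assert shrink_factor(fe, max_fe) == pytest.approx(expected, abs=1e-12)

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            shrink_factor(0, 0)


class TestHungerWeights:
    def test_w1_is_one_when_gate_not_taken(self):
        w1, _ = hunger_weights(50.0, 200.0, 30, l=0.03, r3=0.5, r4=0.9, r5=0.5)
        assert w1 == 1.0

    def test_w1_hungry_branch_closed_form(self):
        w1, _ = hunger_weights(50.0, 200.0, 30, l=0.03, r3=0.01, r4=0.5, r5=0.5)
        assert w1 == pytest.approx(50.0 * 30 / 200.0 * 0.5, abs=1e-12)

    def test_w1_zero_hunger_in_hungry_branch(self):
        w1, _ = hunger_weights(0.0, 200.0, 30, l=0.03, r3=0.0, r4=0.9, r5=0.5)
        assert w1 == 0.0

    def test_w2_vanishes_when_hunger_equals_total(self):
        _, w2 = hunger_weights(200.0, 200.0, 30, l=0.03, r3=0.5, r4=0.5, r5=0.9)
        assert w2 == 0.0

    def test_zero_total_hunger_defaults_w1_to_one(self):
        w1, w2 = hunger_weights(0.0, 0.0, 30, l=0.03, r3=0.0, r4=0.7, r5=0.5)
        assert w1 == 1.0
        assert w2 == 0.0

    @given(st.floats(0, 1e4), st.floats(1e-9, 1e6), st.floats(0, 1),
           st.floats(0, 1), st.floats(0, 1))
    def test_w2_range_invariant(self, hunger, total, r3, r4, r5):
        _, w2 = hunger_weights(hunger, total, 30, 0.03, r3, r4, r5)
        assert 0.0 <= w2 < 2.0


class TestHungerIncrement:
    def test_th_above_lh_passes_through(self):
        # TH = (150-0)/(200-0) * 1.0 * 2 * 200 = 300 >= LH -> H = TH
        h = hunger_increment(150.0, 0.0, 200.0, bounds_range=200.0,
                             lh=100.0, r6=0.5, r=0.3)
        assert h == pytest.approx(150.0, abs=1e-12)

    def test_th_below_lh_floors_at_lh(self):
        h = hunger_increment(1.0, 0.0, 200.0, bounds_range=200.0,
                             lh=100.0, r6=0.01, r=0.25)
        assert h == pytest.approx(100.0 * 1.25, abs=1e-12)

    def test_flat_generation_uses_floor_branch(self):
        h = hunger_increment(5.0, 5.0, 5.0, bounds_range=200.0,
                             lh=100.0, r6=0.9, r=0.0)
        assert h == pytest.approx(100.0, abs=1e-12)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_floor_branch_range(self, r6, r):
        h = hunger_increment(0.0, 0.0, 1.0, 200.0, lh=100.0, r6=r6, r=r)
        assert 100.0 <= h <= 200.0


class TestPositionUpdate:
    def test_selfscale_branch_identity_at_zero_noise(self):
        x = np.array([1.0, -2.0, 3.0])
        out = position_update(x, np.zeros(3), w1=1, w2=1, r_step=0.5, e=0.5,
                              l=0.03, r1=0.0, r2=0.9, z=0.0)
        np.testing.assert_allclose(out, x)

    def test_attraction_vanishes_at_best(self):
        xb = np.array([2.0, -1.0])
        out = position_update(xb.copy(), xb, w1=0.7, w2=1.5, r_step=0.9,
                              e=0.5, l=0.03, r1=0.5, r2=0.9, z=0.0)
        np.testing.assert_allclose(out, 0.7 * xb)

    def test_one_dimensional_worked_case(self):
        # depart branch: 1*2 + 0.5*1*|2-0| = 3
        out = position_update(np.array([0.0]), np.array([2.0]), w1=1.0,
                              w2=1.0, r_step=0.5, e=0.3, l=0.03,
                              r1=0.5, r2=0.9, z=0.0)
        assert out[0] == pytest.approx(3.0, abs=1e-12)

    def test_approach_branch_sign(self):
        out = position_update(np.array([0.0]), np.array([2.0]), w1=1.0,
                              w2=1.0, r_step=0.5, e=0.9, l=0.03,
                              r1=0.5, r2=0.1, z=0.0)
        assert out[0] == pytest.approx(1.0, abs=1e-12)


class TestClamp:
    def test_inside_unchanged(self, space10):
        x = np.linspace(-99, 99, 10)
        np.testing.assert_array_equal(clamp_to_bounds(x, space10), x)

    def test_above_upper_clipped(self, space10):
        x = np.full(10, 105.0)
        np.testing.assert_array_equal(clamp_to_bounds(x, space10),
                                      np.full(10, 100.0))

    def test_below_lower_clipped(self, space10):
        x = np.full(10, -1e9)
        np.testing.assert_array_equal(clamp_to_bounds(x, space10),
                                      space10.lower)


class TestOptimize:
    def test_sphere_2d_converges(self):
        f = make_benchmark("sphere", 2)
        res = optimize(f, HGSParams(n_agents=30, max_fe=5000), rng=3)
        assert res.best_fitness < 1e-6

    def test_fixed_seed_reproducible(self, small_params):
        f = make_benchmark("rastrigin", 5)
        a = optimize(f, small_params, rng=42)
        b = optimize(f, small_params, rng=42)
        assert a.best_fitness == b.best_fitness
        np.testing.assert_array_equal(a.best_position, b.best_position)
        assert a.trace == b.trace

    def test_trace_monotone_and_budget(self, small_params):
        f = make_benchmark("ackley", 4)
        res = optimize(f, small_params, rng=5)
        values = [bf for _, bf in res.trace]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert res.n_evaluations <= small_params.max_fe
        assert res.trace[-1][0] == res.n_evaluations

    def test_positions_stay_in_bounds(self):
        # engine clamps every generation; final best must respect bounds
        f = make_benchmark("schwefel", 3)
        res = optimize(f, HGSParams(n_agents=8, max_fe=400), rng=9)
        assert f.space.contains(res.best_position)

    def test_nonfinite_objective_aborts(self, small_params):
        from mhgs.benchmarks import ObjectiveFunction
        space = SearchSpace(2, -1, 1)
        bad = ObjectiveFunction("bad", space,
                                lambda X: np.full(X.shape[0], np.nan))
        with pytest.raises(RuntimeError, match="non-finite"):
            optimize(bad, small_params, rng=1)
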