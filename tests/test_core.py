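import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ontosense as ons
from ontosense.core import Belief, Cue, CueKind, DevelopmentalState


probs = st.floats(min_value=0.01, max_value=0.99)
reliabilities = st.floats(min_value=0.5, max_value=0.99)


class TestSchedules:
    def test_increasing_ramp_endpoints_and_mean(self):
        s = ons.build_schedule("increasing", 0.55, 0.95, 20)
        assert s.values[0] == pytest.approx(0.55)
        assert s.values[-1] == pytest.approx(0.95)
        steps = np.diff(s.values)
        assert np.allclose(steps, 0.4 / 19)
        assert np.mean(s.values) == pytest.approx(0.75, abs=1e-12)

    def test_decreasing_is_exact_reverse_of_increasing(self):
        inc = ons.build_schedule("increasing", 0.55, 0.95, 20)
        dec = ons.build_schedule("decreasing", 0.55, 0.95, 20)
        assert dec.values == inc.values[::-1]

    def test_triangular_mirrored_halves(self):
        tri = ons.build_schedule("triangular", 0.55, 0.95, 20)
        vals = np.array(tri.values)
        assert np.allclose(vals[:10], np.linspace(0.55, 0.95, 10))
        assert np.allclose(vals[10:], np.linspace(0.55, 0.95, 10)[::-1])
        # peak attained twice, monotone up then down
        assert np.all(np.diff(vals[:10]) >= 0)
        assert np.all(np.diff(vals[10:]) <= 0)

    @pytest.mark.parametrize("r_min,r_max,T", [(0.55, 0.95, 20), (0.55, 0.75, 20), (0.6, 0.9, 8)])
    def test_equal_mean_across_patterns(self, r_min, r_max, T):
        means = [
            np.mean(ons.build_schedule(p, r_min, r_max, T).values)
            for p in ("increasing", "decreasing", "triangular")
        ]
        assert max(means) - min(means) < 1e-9

    def test_min_max_bounds_attained(self):
        for p in ("increasing", "decreasing", "triangular"):
            s = ons.build_schedule(p, 0.55, 0.95, 12)
            assert min(s.values) == pytest.approx(0.55, abs=1e-12)
            assert max(s.values) == pytest.approx(0.95, abs=1e-12)

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(pattern="increasing", r_min=0.4, r_max=0.9, T=10), "0.5"),
            (dict(pattern="increasing", r_min=0.55, r_max=1.0, T=10), "r_max"),
            (dict(pattern="triangular", r_min=0.55, r_max=0.95, T=9), "even"),
            (dict(pattern="sigmoid", r_min=0.55, r_max=0.95, T=10), "pattern"),
        ],
    )
    def test_invalid_schedules_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            ons.build_schedule(**kwargs)

    def test_constant_pattern_repeats_r_min(self):
        s = ons.build_schedule("constant", 0.7, 0.9, 5)
        assert s.values == (0.7,) * 5


class TestBayesianUpdating:
    def test_uniform_prior_posterior_equals_reliability(self):
        s = ons.build_schedule("constant", 0.55, 0.55, 3)
        b = ons.posterior_update(Belief.from_prior(0.5), Cue(CueKind.C0, 1), s)
        assert b.p1 == pytest.approx(0.45, abs=1e-12)

    def test_uninformative_cue_is_identity(self):
        s = ons.build_schedule("constant", 0.5, 0.5, 3)
        for kind in (CueKind.C0, CueKind.C1):
            b = ons.posterior_update(Belief.from_prior(0.5), Cue(kind, 1), s)
            assert b.p1 == pytest.approx(0.5, abs=1e-12)

    def test_hand_computed_single_update(self):
        # odds (0.7/0.3) * (0.75/0.25) = 7  ->  p1 = 7/8
        s = ons.build_schedule("constant", 0.75, 0.75, 3)
        b = ons.posterior_update(Belief.from_prior(0.7), Cue(CueKind.C1, 2), s)
        assert b.p1 == pytest.approx(0.875, abs=1e-9)

    def test_sequence_hand_computations(self):
        s = ons.CueReliabilitySchedule(2, "constant", 0.55, 0.75, (0.55, 0.75))
        b = ons.posterior_from_sequence(
            0.5, [Cue(CueKind.C1, 1), Cue(CueKind.C1, 2)], s
        )
        assert b.p1 == pytest.approx(0.78571, abs=1e-5)
        b = ons.posterior_from_sequence(
            0.5, [Cue(CueKind.C1, 1), Cue(CueKind.C0, 2)], s
        )
        assert b.p1 == pytest.approx(0.28947, abs=1e-5)

    def test_empty_sequence_returns_prior(self):
        s = ons.build_schedule("constant", 0.55, 0.55, 3)
        assert ons.posterior_from_sequence(0.9, [], s).p1 == pytest.approx(0.9)

    def test_duplicate_period_rejected(self):
        s = ons.build_schedule("constant", 0.55, 0.55, 3)
        b = ons.posterior_update(Belief.from_prior(0.5), Cue(CueKind.C1, 1), s)
        with pytest.raises(ValueError, match="period 1"):
            ons.posterior_update(b, Cue(CueKind.C0, 1), s)

    def test_order_invariance_and_period_sensitivity(self):
        s = ons.build_schedule("increasing", 0.55, 0.95, 4)
        cues = [Cue(CueKind.C1, 1), Cue(CueKind.C0, 3), Cue(CueKind.C1, 4)]
        a = ons.posterior_from_sequence(0.6, cues, s)
        b = ons.posterior_from_sequence(0.6, cues[::-1], s)
        assert a.p1 == pytest.approx(b.p1, abs=1e-12)
        assert a.history_key == b.history_key
        # exchanging cue kinds between periods with different r changes p1
        swapped = [Cue(CueKind.C0, 1), Cue(CueKind.C1, 3), Cue(CueKind.C1, 4)]
        c = ons.posterior_from_sequence(0.6, swapped, s)
        assert abs(c.p1 - a.p1) > 1e-6

    @settings(max_examples=200, derandomize=True)
    @given(prior=probs, r=reliabilities)
    def test_martingale_property(self, prior, r):
        # prior-predictive expectation of the posterior equals the prior
        s = ons.CueReliabilitySchedule(1, "constant", 0.5, 0.99, (r,))
        b = Belief.from_prior(prior)
        p_c1 = prior * r + (1 - prior) * (1 - r)
        p1_c1 = ons.posterior_update(b, Cue(CueKind.C1, 1), s).p1
        p1_c0 = ons.posterior_update(b, Cue(CueKind.C0, 1), s).p1
        assert p_c1 * p1_c1 + (1 - p_c1) * p1_c0 == pytest.approx(prior, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(prior=probs, r=reliabilities, kind=st.booleans())
    def test_complement_symmetry(self, prior, r, kind):
        # flipping the cue kind and the prior maps p1 to 1 - p1
        s = ons.CueReliabilitySchedule(1, "constant", 0.5, 0.99, (r,))
        k = CueKind.C1 if kind else CueKind.C0
        flip = CueKind.C0 if kind else CueKind.C1
        a = ons.posterior_update(Belief.from_prior(prior), Cue(k, 1), s).p1
        b = ons.posterior_update(Belief.from_prior(1 - prior), Cue(flip, 1), s).p1
        assert a == pytest.approx(1 - b, abs=1e-12)

    def test_belief_log_odds_consistency(self):
        s = ons.build_schedule("increasing", 0.55, 0.95, 6)
        b = ons.posterior_from_sequence(
            0.7, [Cue(CueKind.C1, 2), Cue(CueKind.C0, 5)], s
        )
        assert b.p1 == pytest.approx(1 / (1 + math.exp(-b.log_odds)), abs=1e-12)


class TestFitness:
    def test_linear_unit_slope(self):
        f = ons.marginal_fitness_function("linear", 20.0, 20)
        assert f(7) == pytest.approx(7.0)
        assert f(0) == 0.0 and f(20) == pytest.approx(20.0)

    def test_diminishing_concave(self):
        # concave: above the unit chord on (0, T), strictly decreasing marginals
        f = ons.marginal_fitness_function("diminishing", 20.0, 20)
        assert f(1) > 1 and f(19) > 19 and f(20) == pytest.approx(20.0)
        marginals = np.diff([f(y) for y in range(21)])
        assert np.all(np.diff(marginals) < 0)

    def test_accelerating_convex(self):
        # convex: below the unit chord on (0, T), strictly increasing marginals
        f = ons.marginal_fitness_function("accelerating", 20.0, 20)
        assert f(1) < 1 and f(19) < 19 and f(20) == pytest.approx(20.0)
        marginals = np.diff([f(y) for y in range(21)])
        assert np.all(np.diff(marginals) > 0)

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ons.marginal_fitness_function("cubic", 20.0, 20)

    def test_symmetric_posterior_cancels_to_baseline(self):
        m = ons.FitnessMapping(max_payoff=20.0, baseline=3.0)
        for y0, y1 in [(0, 0), (5, 5), (3, 11), (20, 0)]:
            assert ons.terminal_fitness(y0, y1, 0.5, m, 20) == pytest.approx(3.0)

    def test_perfect_match_earns_max_payoff(self):
        m = ons.FitnessMapping(max_payoff=20.0, baseline=0.0)
        v = ons.terminal_fitness(0, 20, 1 - 1e-13, m, 20)
        assert v == pytest.approx(20.0, abs=1e-9)

    def test_hand_computed_terminal_value(self):
        m = ons.FitnessMapping(max_payoff=20.0, baseline=0.0)
        assert ons.terminal_fitness(3, 7, 0.8, m, 20) == pytest.approx(2.4)

    def test_baseline_shifts_all_values_equally(self):
        lo = ons.FitnessMapping(max_payoff=20.0, baseline=0.0)
        hi = ons.FitnessMapping(max_payoff=20.0, baseline=5.0)
        for y0, y1, p in [(0, 0, 0.5), (4, 9, 0.8), (12, 2, 0.3)]:
            assert ons.terminal_fitness(y0, y1, p, hi, 20) - ons.terminal_fitness(
                y0, y1, p, lo, 20
            ) == pytest.approx(5.0)

    def test_counter_overflow_rejected(self):
        m = ons.FitnessMapping(max_payoff=20.0)
        with pytest.raises(ValueError, match="exceeds"):
            ons.terminal_fitness(15, 10, 0.5, m, 20)

    def test_default_baseline_keeps_fitness_nonnegative(self):
        m = ons.FitnessMapping(max_payoff=20.0)
        assert m.baseline == 20.0
        assert ons.terminal_fitness(20, 0, 1 - 1e-13, m, 20) >= -1e-9


class TestDevelopmentalState:
    def test_counter_conservation_enforced(self):
        s = ons.build_schedule("constant", 0.6, 0.6, 3)
        b = ons.posterior_from_sequence(
            0.5, [Cue(CueKind.C1, 1), Cue(CueKind.C0, 2)], s
        )
        DevelopmentalState(t=2, belief=b, y0=1, y1=0, yw=1)
        with pytest.raises(ValueError, match="sum"):
            DevelopmentalState(t=2, belief=b, y0=1, y1=1, yw=1)

    def test_belief_history_length_must_match_t(self):
        b = Belief.from_prior(0.5)
        with pytest.raises(ValueError, match="cues"):
            DevelopmentalState(t=1, belief=b, y0=1, y1=0, yw=0)
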