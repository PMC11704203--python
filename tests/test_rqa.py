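import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfdyn import (
    ER_STATES,
    NONE_STATE,
    BehaviourSequence,
    block_entropy,
    build_recurrence_plot,
    laminarity,
    recurrence_rate,
    rqa_measures,
    trapping_time,
    vertical_lines,
)
from sfdyn.rqa import block_areas
from sfdyn.synth import BehaviourScenario, gen_behaviour_sequence

import oracles

A, B = "oral_tactile", "distancing"


def seq(*states):
    return np.array(states, dtype=object)


class TestBuildRecurrencePlot:
    def test_all_none_has_no_recurrences(self):
        rp = build_recurrence_plot(seq(*[NONE_STATE] * 10))
        assert rp.n_recurrent == 0

    def test_hand_enumerated_t4(self):
        # (A, A, none, A): pairs {(0,1),(0,3),(1,3)} and symmetric partners
        rp = build_recurrence_plot(seq(A, A, NONE_STATE, A), loi_excluded=True)
        expected = {(0, 1), (0, 3), (1, 3), (1, 0), (3, 0), (3, 1)}
        assert {tuple(ij) for ij in np.argwhere(rp.R)} == expected
        assert rp.n_recurrent == 6

    def test_single_state_full_recurrence(self):
        rp = build_recurrence_plot(seq(*[A] * 120), loi_excluded=True)
        assert rp.n_recurrent == 120 * 120 - 120 == 14280

    def test_symmetry(self, rng):
        states = rng.choice(list(ER_STATES) + [NONE_STATE], size=60)
        rp = build_recurrence_plot(seq(*states))
        assert np.array_equal(rp.R, rp.R.T)

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="unknown state"):
            build_recurrence_plot(seq(A, "sleeping"))

    def test_loi_included_keeps_diagonal(self):
        rp = build_recurrence_plot(seq(A, A), loi_excluded=False)
        assert rp.n_recurrent == 4


class TestRecurrenceRate:
    def test_single_state_is_100(self):
        rp = build_recurrence_plot(seq(*[A] * 120))
        assert recurrence_rate(rp) == pytest.approx(100.0)

    def test_all_none_is_0(self):
        rp = build_recurrence_plot(seq(*[NONE_STATE] * 120))
        assert recurrence_rate(rp) == 0.0

    def test_t4_example_is_50(self):
        rp = build_recurrence_plot(seq(A, A, NONE_STATE, A))
        assert recurrence_rate(rp) == pytest.approx(100 * 6 / 12)

    def test_t1_with_loi_excluded_rejected(self):
        rp = build_recurrence_plot(seq(A))
        with pytest.raises(ValueError, match="undefined"):
            recurrence_rate(rp)


class TestVerticalLines:
    def test_single_state_t5_split_by_diagonal(self):
        rp = build_recurrence_plot(seq(*[A] * 5), loi_excluded=True)
        got = sorted(vertical_lines(rp))
        naive = oracles.naive_rqa([A] * 5, set(ER_STATES))
        assert got == sorted(naive["lines"])
        # per column the length-4 run is split (k, 4-k) by the LOI gap
        assert got == sorted([4, 1, 3, 2, 2, 3, 1, 4])

    def test_alternating_all_runs_length_1(self):
        states = [A, NONE_STATE] * 10
        rp = build_recurrence_plot(seq(*states))
        assert set(vertical_lines(rp)) == {1}

    def test_block_of_three(self):
        states = [A, A, A] + [NONE_STATE] * 7
        rp = build_recurrence_plot(seq(*states))
        lines = vertical_lines(rp)
        naive = oracles.naive_rqa(states, set(ER_STATES))
        assert sorted(lines) == sorted(naive["lines"])

    def test_sum_equals_recurrent_points(self, rng):
        states = rng.choice(list(ER_STATES) + [NONE_STATE], size=80)
        rp = build_recurrence_plot(seq(*states))
        assert sum(vertical_lines(rp)) == rp.n_recurrent


class TestScalarMeasures:
    def test_laminarity_all_singletons(self):
        assert laminarity([1, 1, 1], 3) == 0.0

    def test_laminarity_all_laminar(self):
        assert laminarity([3, 4, 5], 12) == pytest.approx(100.0)

    def test_laminarity_arithmetic(self):
        assert laminarity([3, 1, 1], 5) == pytest.approx(60.0)

    def test_laminarity_no_points(self):
        assert laminarity([], 0) == 0.0

    def test_trapping_time_mean(self):
        assert trapping_time([3, 5]) == pytest.approx(4.0)

    def test_trapping_time_missing_below_threshold(self):
        assert math.isnan(trapping_time([2, 2], v_min=3))


class TestBlockEntropy:
    def test_equal_bouts_zero(self):
        # all ER bouts length 2 -> every block is 2x2 -> single bin
        states = [A, A, NONE_STATE, A, A, NONE_STATE, B, B]
        rp = build_recurrence_plot(seq(*states))
        assert block_entropy(rp) == 0.0

    def test_two_equal_frequency_sizes_one_bit(self):
        # A-bouts of length 2 (blocks 4), B-bouts of length 3 (blocks 9)
        states = [A, A, NONE_STATE, A, A, NONE_STATE, B, B, B, NONE_STATE, B, B, B]
        rp = build_recurrence_plot(seq(*states))
        assert block_entropy(rp) == pytest.approx(1.0)

    def test_no_blocks_missing(self):
        rp = build_recurrence_plot(seq(*[NONE_STATE] * 5))
        assert math.isnan(block_entropy(rp))

    def test_block_areas_sum_to_recurrent_points_with_loi(self, rng):
        states = rng.choice(list(ER_STATES) + [NONE_STATE], size=100)
        rp_loi = build_recurrence_plot(seq(*states), loi_excluded=False)
        rp = build_recurrence_plot(seq(*states), loi_excluded=True)
        assert sum(block_areas(rp, loi_in_blocks=True)) == rp_loi.n_recurrent
        assert sum(block_areas(rp, loi_in_blocks=False)) == rp.n_recurrent

    def test_geometric_bouts_exceed_fixed_bouts(self):
        # mixed bout lengths produce strictly more block-size diversity
        probs = {**{s: 0.0 for s in ER_STATES}, A: 0.5, NONE_STATE: 0.5}
        for s in range(20):
            fixed = gen_behaviour_sequence(
                BehaviourScenario(state_probs=probs, mean_bout_s=4,
                                  bout_dist="fixed", seed=s)
            )
            geom = gen_behaviour_sequence(
                BehaviourScenario(state_probs=probs, mean_bout_s=4,
                                  bout_dist="geometric", seed=s)
            )
            e_fixed = block_entropy(build_recurrence_plot(fixed))
            e_geom = block_entropy(build_recurrence_plot(geom))
            assert e_geom > e_fixed


class TestRQAMeasures:
    def test_all_none(self):
        m = rqa_measures(seq(*[NONE_STATE] * 120))
        assert m.rr == 0.0
        assert m.lam == 0.0
        assert math.isnan(m.tt)
        assert math.isnan(m.entb)

    def test_single_state_rr_100(self):
        m = rqa_measures(seq(*[A] * 120))
        assert m.rr == pytest.approx(100.0)

    def test_oracle_equivalence_random_t50(self, rng):
        targets = set(ER_STATES)
        for _ in range(25):
            states = rng.choice(list(ER_STATES) + [NONE_STATE], size=50).tolist()
            m = rqa_measures(seq(*states))
            o = oracles.naive_rqa(states, targets)
            assert m.rr == pytest.approx(o["rr"], abs=1e-12)
            assert m.lam == pytest.approx(o["lam"], abs=1e-12)
            if o["tt"] is None:
                assert math.isnan(m.tt)
            else:
                assert m.tt == pytest.approx(o["tt"], abs=1e-12)
            if o["entb"] is None:
                assert math.isnan(m.entb)
            else:
                assert m.entb == pytest.approx(o["entb"], abs=1e-12)

    def test_relabel_invariance(self, rng):
        states = rng.choice(list(ER_STATES) + [NONE_STATE], size=80)
        perm = dict(zip(ER_STATES, np.roll(np.array(ER_STATES, dtype=object), 2)))
        perm[NONE_STATE] = NONE_STATE
        relabeled = np.array([perm[s] for s in states], dtype=object)
        m1 = rqa_measures(seq(*states))
        m2 = rqa_measures(seq(*relabeled))
        assert m1.rr == pytest.approx(m2.rr)
        assert m1.lam == pytest.approx(m2.lam)

    def test_rr_monotone_in_er_occupancy(self, rng):
        states = rng.choice([A, NONE_STATE], size=100, p=[0.4, 0.6])
        rr_prev = rqa_measures(seq(*states)).rr
        none_idx = np.flatnonzero(states == NONE_STATE)
        for idx in none_idx[:10]:
            states = states.copy()
            states[idx] = A  # most common ER state
            rr = rqa_measures(seq(*states)).rr
            assert rr >= rr_prev
            rr_prev = rr

    @given(st.lists(st.sampled_from([A, B, NONE_STATE]), min_size=2, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence_short_sequences(self, states):
        m = rqa_measures(seq(*states))
        o = oracles.naive_rqa(states, set(ER_STATES))
        assert m.rr == pytest.approx(o["rr"], abs=1e-12)
        assert m.lam == pytest.approx(o["lam"], abs=1e-12)


class TestBehaviourSequence:
    def test_alphabet_enforced(self):
        with pytest.raises(ValueError, match="unknown state"):
            BehaviourSequence(states=np.array(["crawling"], dtype=object))

    def test_length_property(self):
        s = BehaviourSequence(states=seq(*[A] * 120), phase="SF1")
        assert s.T == 120
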