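import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lakeq.qcore import (
    ArctanSchedule,
    ConstantSchedule,
    TripleQState,
    greedy_policy,
    learn_mdp,
    mean_reward,
    select_action,
    update,
)


class TestEpsilonSchedule:
    def test_derived_value_at_first_episode(self):
        sched = ArctanSchedule(scale=0.2, offset=0.0)
        assert sched(1) == pytest.approx(2 / np.pi * np.arctan(0.2), abs=1e-12)
        assert sched(1) == pytest.approx(0.1257, abs=2e-4)

    def test_strictly_increasing_and_bounded(self):
        sched = ArctanSchedule()
        eps = np.array([sched(u) for u in range(1, 10_001)])
        assert (np.diff(eps) > 0).all()
        assert eps[0] >= 0.0 and eps[-1] < 1.0

    def test_asymptote_approaches_one(self):
        assert ArctanSchedule()(10**7) > 0.9999

    def test_rejects_non_positive_episode(self):
        with pytest.raises(ValueError):
            ArctanSchedule()(0)
        with pytest.raises(ValueError):
            ConstantSchedule()(0)

    def test_rejects_non_positive_scale(self):
        with pytest.raises(ValueError):
            ArctanSchedule(scale=0.0)


class TestMeanReward:
    def test_perfect_prediction_is_zero(self):
        assert mean_reward([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_arithmetic(self):
        assert mean_reward([1.0, 2.0], [0.0, 4.0]) == pytest.approx(-1.5)

    def test_single_indicator_reduces_to_negative_abs(self):
        assert mean_reward([2.0], [5.5]) == pytest.approx(-3.5)

    def test_never_positive(self, rng):
        for _ in range(50):
            y, p = rng.standard_normal(6), rng.standard_normal(6)
            assert mean_reward(y, p) <= 0

    @given(
        y=st.lists(st.floats(-100, 100), min_size=1, max_size=8),
        shift=st.floats(-50, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_translation_invariance(self, y, shift):
        y = np.asarray(y)
        p = y + 1.0
        assert mean_reward(y + shift, p + shift) == pytest.approx(
            mean_reward(y, p), abs=1e-9
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="indicators"):
            mean_reward([1.0, 2.0], [1.0])


class TestSelectAction:
    def test_pure_exploitation_is_argmax(self, rng):
        q = TripleQState.zeros(2, 3)
        q.q_star[:] = [[0.1, 0.9, 0.2], [0.7, 0.1, 0.2]]
        actions = {select_action(q, 0, 1.0, rng) for _ in range(100)}
        assert actions == {1}

    def test_pure_exploration_is_uniform(self, rng):
        q = TripleQState.zeros(1, 4)
        q.q_star[0] = [0.0, 10.0, 0.0, 0.0]  # argmax must be irrelevant
        n = 10_000
        counts = np.bincount(
            [select_action(q, 0, 0.0, rng) for _ in range(n)], minlength=4
        )
        # three-sigma binomial band around n/4
        sigma = np.sqrt(n * 0.25 * 0.75)
        assert (np.abs(counts - n / 4) < 3 * sigma).all()

    def test_tie_break_lowest_index(self, rng):
        q = TripleQState.zeros(1, 3)
        q.q_star[0] = [0.5, 0.9, 0.9]
        assert select_action(q, 0, 1.0, rng) == 1


def _expected_cell_after_update(q1, q2, q3, q_star, s, a, r, s2, alpha, gamma, c):
    """Loop-free arithmetic oracle for a single cell update."""
    vals = []
    for qi in (q1, q2, q3):
        target = r + gamma * max(qi[s2])
        vals.append(q_star[s][a] + alpha * (target - q_star[s][a]))
    ave, mn = sum(vals) / 3, min(vals)
    lam = abs(ave - mn) / (c + abs(ave - mn))
    return vals, lam * ave + (1 - lam) * mn


class TestUpdate:
    def test_zero_tables_zero_reward_fixed_point(self):
        q = TripleQState.zeros(3, 3)
        update(q, 1, 2, 0.0, 2)
        for table in (*q.tables, q.q_star):
            np.testing.assert_array_equal(table, 0.0)

    def test_constant_reward_chain_converges_to_bellman_fixed_point(self):
        q = TripleQState.zeros(1, 1, alpha=0.1, gamma=0.9)
        for _ in range(3000):
            update(q, 0, 0, -1.0, 0)
        assert q.q_star[0, 0] == pytest.approx(-10.0, abs=1e-3)

    def test_equal_tables_stay_equal_with_zero_weight(self, rng):
        q = TripleQState.zeros(2, 2)
        for _ in range(50):
            update(q, int(rng.integers(2)), int(rng.integers(2)),
                   float(rng.normal()), int(rng.integers(2)))
        np.testing.assert_array_equal(q.q1, q.q2)
        np.testing.assert_array_equal(q.q2, q.q3)
        np.testing.assert_array_equal(q.q_star, q.q1)

    def test_distinct_tables_match_arithmetic_oracle(self):
        q = TripleQState(
            q1=np.array([[0.4, -0.2], [0.1, 0.9]]),
            q2=np.array([[0.1, 0.3], [-0.5, 0.2]]),
            q3=np.array([[-0.3, 0.8], [0.2, 0.0]]),
            q_star=np.array([[0.05, 0.2], [-0.1, 0.3]]),
            alpha=0.2, gamma=0.8, c=1.5,
        )
        before = {k: v.tolist() for k, v in
                  [("q1", q.q1), ("q2", q.q2), ("q3", q.q3), ("qs", q.q_star)]}
        vals, expected_star = _expected_cell_after_update(
            before["q1"], before["q2"], before["q3"], before["qs"],
            0, 1, -0.7, 1, 0.2, 0.8, 1.5,
        )
        update(q, 0, 1, -0.7, 1)
        for qi, expected in zip(q.tables, vals):
            assert qi[0, 1] == pytest.approx(expected, abs=1e-12)
        assert q.q_star[0, 1] == pytest.approx(expected_star, abs=1e-12)

    @given(
        rewards=st.lists(st.floats(-10, 10), min_size=1, max_size=60),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=60, deadline=None)
    def test_weight_and_combined_value_invariants(self, rewards, seed):
        """After every update lambda is in [0, 1) and Q* lies between the
        cellwise minimum and mean of the three estimates."""
        rng = np.random.default_rng(seed)
        q = TripleQState.zeros(3, 3, c=0.7)
        # perturb tables so the three estimates genuinely differ
        q.q1 += rng.normal(scale=0.5, size=(3, 3))
        q.q2 += rng.normal(scale=0.5, size=(3, 3))
        q.q3 += rng.normal(scale=0.5, size=(3, 3))
        stacked = np.stack(q.tables)
        ave, mn = stacked.mean(axis=0), stacked.min(axis=0)
        lam = np.abs(ave - mn) / (q.c + np.abs(ave - mn))
        q.q_star[:] = lam * ave + (1 - lam) * mn
        for r in rewards:
            s, a, s2 = rng.integers(3, size=3)
            update(q, int(s), int(a), float(r), int(s2))
            stacked = np.stack(q.tables)
            ave, mn = stacked.mean(axis=0), stacked.min(axis=0)
            gap = np.abs(ave - mn)
            lam = gap / (q.c + gap)
            assert ((lam >= 0) & (lam < 1)).all()
            assert (q.q_star >= mn - 1e-12).all()
            assert (q.q_star <= ave + 1e-12).all()

    def test_non_finite_reward_rejected(self):
        q = TripleQState.zeros(1, 1)
        with pytest.raises(ValueError, match="reward"):
            update(q, 0, 0, float("nan"), 0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            TripleQState.zeros(1, 1, alpha=0.0)
        with pytest.raises(ValueError):
            TripleQState.zeros(1, 1, gamma=1.0)
        with pytest.raises(ValueError):
            TripleQState.zeros(1, 1, c=0.0)


class TestGreedyPolicy:
    def test_diagonal_preference(self):
        q = TripleQState.zeros(3, 3)
        q.q_star[:] = np.eye(3)
        np.testing.assert_array_equal(greedy_policy(q), [0, 1, 2])

    def test_all_equal_breaks_to_first_action(self):
        q = TripleQState.zeros(4, 3)
        np.testing.assert_array_equal(greedy_policy(q), 0)

    def test_matches_row_scan_oracle(self, rng):
        for _ in range(20):
            q = TripleQState.zeros(5, 4)
            q.q_star[:] = rng.standard_normal((5, 4))
            expected = [max(range(4), key=lambda a: (q.q_star[s, a], -a))
                        for s in range(5)]
            np.testing.assert_array_equal(greedy_policy(q), expected)


class TestLearnMDP:
    def test_early_stop_on_stable_policy(self):
        rewards = np.array([[1.0, -1.0], [-1.0, 1.0]])
        transitions = np.tile(np.arange(2), (2, 1))
        res = learn_mdp(rewards, transitions, ArctanSchedule(), n_episodes=500,
                        steps_per_episode=50, seed=0, patience=25)
        assert res.episodes_run < 500
        np.testing.assert_array_equal(greedy_policy(res.q), [0, 1])

    def test_serialization_round_trip(self, tmp_path):
        res = learn_mdp(np.array([[0.5, -0.5]]), np.zeros((1, 2), dtype=int),
                        ConstantSchedule(0.8), 20, 20, seed=1)
        res.q.save(tmp_path)
        loaded = TripleQState.load(tmp_path)
        np.testing.assert_array_equal(loaded.q_star, res.q.q_star)
        assert loaded.alpha == res.q.alpha
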