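"""Value updating, softmax choice, replay likelihoods, agent simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import (
    brute_force_nll_test,
    brute_force_nll_training,
    make_test_trial,
    make_training_trial,
    random_test_log,
    random_training_log,
)
from pstlearn.qlearning import (
    ModelParams,
    choice_probability,
    nll_test,
    nll_training,
    replay_training,
    simulate_agent,
    update_q,
)
from pstlearn.task import DEFAULT_CONTINGENCIES, TaskConfig

unit = st.floats(0.0, 1.0, allow_nan=False)


class TestUpdateQ:
    @pytest.mark.parametrize(
        "q,r,a_app,a_av,expected",
        [
            (0.5, 1, 0.3, 0.0, 0.65),
            (0.5, 0, 0.0, 0.1, 0.45),
            (0.8, 1, 0.0, 0.5, 0.8),  # zero-rate identity on a positive outcome
        ],
    )
    def test_one_step(self, q, r, a_app, a_av, expected):
        params = ModelParams.approach_avoid(a_app, a_av, 1.0)
        assert update_q(q, r, params) == pytest.approx(expected)

    def test_hand_recursion(self):
        # q0=0.5, outcomes (1,1,0), both rates 0.2: 0.5 -> 0.6 -> 0.68 -> 0.544
        params = ModelParams.approach_avoid(0.2, 0.2, 1.0)
        q = 0.5
        expected = [0.6, 0.68, 0.544]
        for r, e in zip((1, 1, 0), expected):
            q = update_q(q, r, params)
            assert q == pytest.approx(e, abs=1e-12)

    def test_invalid_outcome(self):
        params = ModelParams.approach_avoid(0.2, 0.2, 1.0)
        with pytest.raises(ValueError, match="outcome"):
            update_q(0.5, 2, params)

    @settings(derandomize=True, max_examples=200)
    @given(q=unit, a_app=unit, a_av=unit, r=st.integers(0, 1))
    def test_q_stays_bounded(self, q, a_app, a_av, r):
        params = ModelParams.approach_avoid(a_app, a_av, 1.0)
        assert 0.0 <= update_q(q, r, params) <= 1.0

    def test_rectified_form_equals_outcome_gating(self):
        # with binary r and q in [0, 1] the two-term rectified update equals
        # "alpha_approach iff r=1" -- exhaustively on a grid
        grid = np.linspace(0, 1, 21)
        for q in grid:
            for a_app in grid[::4]:
                for a_av in grid[::4]:
                    params = ModelParams.approach_avoid(a_app, a_av, 1.0)
                    for r in (0, 1):
                        two_term = q + a_app * max(r - q, 0) + a_av * min(r - q, 0)
                        gated = q + (a_app if r == 1 else a_av) * (r - q)
                        assert update_q(q, r, params) == pytest.approx(two_term, abs=1e-15)
                        assert two_term == pytest.approx(gated, abs=1e-15)


class TestChoiceProbability:
    def test_symmetry(self):
        for beta in (0.01, 0.5, 10):
            assert choice_probability(0.4, 0.4, beta) == pytest.approx(0.5)

    def test_closed_form(self):
        assert choice_probability(0.8, 0.2, 0.3) == pytest.approx(
            1 / (1 + math.exp(-2)), abs=1e-10
        )

    def test_exploitation_limit(self):
        assert choice_probability(0.6, 0.4, 1e-4) > 0.999999

    def test_numerically_stable_at_extreme_ratio(self):
        p = choice_probability(1.0, 0.0, 1 / 700)  # exponent 700
        assert 0.0 < p <= 1.0 and np.isfinite(p)
        p = choice_probability(0.0, 1.0, 1 / 700)
        assert 0.0 < p < 1e-200

    def test_invalid_beta(self):
        with pytest.raises(ValueError, match="beta"):
            choice_probability(0.5, 0.5, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(qa=unit, qb=unit, beta=st.floats(0.01, 10, allow_nan=False))
    def test_normalization_antisymmetry(self, qa, qb, beta):
        assert choice_probability(qa, qb, beta) + choice_probability(qb, qa, beta) == pytest.approx(1.0, abs=1e-12)


class TestReplay:
    def test_empty_log_is_identity(self):
        params = ModelParams.approach_avoid(0.3, 0.1, 0.2)
        state, probs = replay_training([], params, q0=0.4)
        assert all(v == 0.4 for v in state.q.values())
        assert probs.size == 0

    def test_no_learning_gives_chance_probabilities(self):
        params = ModelParams.approach_avoid(0.0, 0.0, 0.5)
        rng = np.random.default_rng(0)
        trials = random_training_log(rng, 20)
        _, probs = replay_training(trials, params)
        assert np.allclose(probs, 0.5)

    def test_three_trial_hand_computation(self):
        params = ModelParams.approach_avoid(0.4, 0.2, 0.25)
        trials = [
            make_training_trial("p", 0, "AB", "A", 1),
            make_training_trial("p", 1, "AB", "A", 0),
            make_training_trial("p", 2, "AB", "B", 0),
        ]
        # p1 = 0.5; qA: 0.5 -> 0.7 (r=1, a=.4) -> 0.56 (r=0, a=.2); qB = 0.5
        p2 = 1 / (1 + math.exp(-(0.7 - 0.5) / 0.25))
        p3 = 1 / (1 + math.exp(-(0.5 - 0.56) / 0.25))
        state, probs = replay_training(trials, params)
        assert probs == pytest.approx([0.5, p2, p3], abs=1e-12)
        assert state.q["A"] == pytest.approx(0.56, abs=1e-12)
        assert state.q["B"] == pytest.approx(0.4, abs=1e-12)

    def test_out_of_order_raises(self):
        trials = [
            make_training_trial("p", 1, "AB", "A", 1),
            make_training_trial("p", 0, "AB", "A", 1),
        ]
        params = ModelParams.approach_avoid(0.3, 0.1, 0.2)
        with pytest.raises(ValueError, match="order"):
            replay_training(trials, params)


class TestLikelihoods:
    def test_chance_closed_form(self):
        params = ModelParams.approach_avoid(0.0, 0.0, 0.5)
        trials = random_training_log(np.random.default_rng(1), 37)
        assert nll_training(trials, params) == pytest.approx(37 * math.log(2), abs=1e-9)

    def test_single_trial_value(self):
        # a single test trial scored at p = 1/(1+e^-2): nll = -ln p = 0.12693;
        # values engineered via one positive A and one negative C training
        # trial at rate 0.6: qA = 0.8, qC = 0.2
        train = [
            make_training_trial("p", 0, "AB", "A", 1),
            make_training_trial("p", 1, "CD", "C", 0),
        ]
        test = [make_test_trial("p", 0, "AC", "A")]
        params = ModelParams.approach_avoid(0.6, 0.6, 0.3)
        assert nll_test(train, test, params) == pytest.approx(0.1269280110429726, abs=1e-10)

    def test_additive_over_trials(self):
        params = ModelParams.approach_avoid(0.3, 0.1, 0.2)
        log = random_training_log(np.random.default_rng(2), 8)
        total = nll_training(log, params)
        _, probs = replay_training(log, params)
        assert total == pytest.approx(float(-np.log(probs).sum()), abs=1e-10)

    def test_equal_final_values_give_chance_test_nll(self):
        params = ModelParams.approach_avoid(0.0, 0.0, 0.4)
        train = random_training_log(np.random.default_rng(3), 12)
        test = random_test_log(np.random.default_rng(4), 10)
        assert nll_test(train, test, params) == pytest.approx(10 * math.log(2), abs=1e-9)

    def test_beta_does_not_move_final_values(self):
        train = random_training_log(np.random.default_rng(5), 15)
        q1, _ = replay_training(train, ModelParams.approach_avoid(0.3, 0.1, 0.1))
        q2, _ = replay_training(train, ModelParams.approach_avoid(0.3, 0.1, 5.0))
        assert q1.q == q2.q

    def test_brute_force_oracle_small_logs(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            a_app, a_av = rng.uniform(0.05, 0.9, 2)
            beta = rng.uniform(0.05, 2.0)
            train = random_training_log(rng, int(rng.integers(2, 11)))
            test = random_test_log(rng, int(rng.integers(1, 7)))
            assert nll_training(train, ModelParams.approach_avoid(a_app, a_av, beta)) == pytest.approx(
                brute_force_nll_training(train, a_app, a_av, beta), abs=1e-10
            )
            assert nll_test(train, test, ModelParams.approach_avoid(a_app, a_av, beta)) == pytest.approx(
                brute_force_nll_test(train, test, a_app, a_av, beta), abs=1e-10
            )


class TestSimulateAgent:
    def test_deterministic_given_seed(self, default_config, typical_params):
        logs = [
            simulate_agent(typical_params, default_config, np.random.default_rng(9))
            for _ in range(2)
        ]
        assert logs[0].trials == logs[1].trials
        assert logs[0].excluded == logs[1].excluded

    def test_greedy_limit_with_deterministic_feedback(self):
        contingencies = {"A": 1.0, "B": 0.0, "C": 1.0, "D": 0.0, "E": 1.0, "F": 0.0}
        cfg = TaskConfig(contingencies=contingencies)
        params = ModelParams.approach_avoid(0.5, 0.5, 1e-5)
        log = simulate_agent(params, cfg, np.random.default_rng(11))
        ab = [t for t in log.training if t.pair.key == "AB"]
        assert all(t.chosen == "A" for t in ab[1:])

    def test_log_satisfies_trial_invariants(self, agent_log):
        assert all(t.outcome in (0, 1) for t in agent_log.training)
        assert all(t.outcome is None for t in agent_log.test)
        assert len(agent_log.test) == 96

    def test_learned_preference_for_rewarded_symbol(self, default_config):
        # agents at typical fitted parameters should select A above chance
        params = ModelParams.approach_avoid(0.28, 0.08, 0.26)
        rng = np.random.default_rng(13)
        rates = []
        for _ in range(100):
            log = simulate_agent(params, default_config, rng)
            a_trials = [t for t in log.test if "A" in t.pair.symbols]
            rates.append(np.mean([t.chosen == "A" for t in a_trials]))
        assert np.mean(rates) > 0.5
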