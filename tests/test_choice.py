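import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import foragekit as fk
from foragekit.choice import (
    DisplayContext,
    SessionLikelihood,
    _perm_table,
    softmax_probabilities,
)
from foragekit.environment import START_INDEX
from foragekit.exceptions import (
    LikelihoodError,
    NoCandidatesError,
    NonpositiveTimeError,
)

from conftest import naive_lookahead_cost, naive_step_cost


def params_with(**kw):
    base = dict(beta=0.05, w1=500.0, gamma=1.0, w2=1000.0, lookahead_n=1)
    base.update(kw)
    return fk.ChoiceModelParams(**base)


class TestRewardRate:
    def test_simple(self):
        assert fk.reward_rate(12, 1.0) == pytest.approx(12.0)

    def test_hand_example(self):
        assert fk.reward_rate(15, 0.26) == pytest.approx(57.69, abs=0.01)

    def test_eye_example(self):
        assert fk.reward_rate(10, 0.354) == pytest.approx(28.25, abs=0.01)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(NonpositiveTimeError):
            fk.reward_rate(10, 0.0)


class TestStepCost:
    def test_all_flags_off_zero(self, hand_mm):
        d = fk.generate_display("value", 0)
        p = params_with(include_reward_rate=False, include_distance=False,
                        include_size=False)
        for j in range(5):
            assert fk.step_cost(p, START_INDEX, j, d, hand_mm) == 0.0

    def test_reward_rate_only(self, hand_mm):
        # engineered: zero-jitter display, start -> central first-row target
        d = fk.generate_display("value", 0, jitter=0.0)
        j = next(t.id for t in d.targets if t.id == 2)
        v = d.targets[j].value
        p = params_with(include_distance=False, include_size=False)
        t = 0.2 + 1.0 * 0.06
        assert fk.step_cost(p, START_INDEX, j, d, hand_mm) == pytest.approx(-v / t)

    def test_distance_term_example(self, hand_mm):
        d = fk.generate_display("value", 0, jitter=0.0)
        p = params_with(w1=100.0, gamma=1.0, include_reward_rate=False,
                        include_size=False)
        assert fk.step_cost(p, START_INDEX, 2, d, hand_mm) == pytest.approx(6.0)

    def test_matches_naive(self, hand_mm):
        d = fk.generate_display("small_high", 11)
        p = params_with(gamma=1.3)
        for j in (0, 5, 14):
            assert fk.step_cost(p, START_INDEX, j, d, hand_mm) == pytest.approx(
                naive_step_cost(p, START_INDEX, j, d, hand_mm)
            )


class TestLookaheadCost:
    def test_depth_one_equals_step_cost(self, hand_mm):
        d = fk.generate_display("small_low", 4)
        p = params_with()
        for j in (0, 7):
            assert fk.lookahead_cost(p, START_INDEX, j, d, hand_mm) == pytest.approx(
                fk.step_cost(p, START_INDEX, j, d, hand_mm)
            )

    def test_zero_lambdas_equal_step_cost(self, hand_mm):
        d = fk.generate_display("small_low", 4)
        p = params_with(lambdas=(0.0, 0.0, 0.0), lookahead_n=4)
        for j in (1, 9):
            assert fk.lookahead_cost(p, START_INDEX, j, d, hand_mm) == pytest.approx(
                fk.step_cost(p, START_INDEX, j, d, hand_mm)
            )

    def test_small_instance_brute_force(self, hand_mm):
        d = fk.generate_display("value", 8)
        for t in d.targets[:-4]:
            t.harvested = True  # 4 remain
        p = params_with(lambdas=(0.7, 0.4), lookahead_n=3)
        for t in d.targets[-4:]:
            got = fk.lookahead_cost(p, START_INDEX, t.id, d, hand_mm)
            want = naive_lookahead_cost(p, START_INDEX, t.id, d, hand_mm)
            assert got == pytest.approx(want)

    def test_horizon_truncates_to_remaining(self, hand_mm):
        d = fk.generate_display("value", 8)
        for t in d.targets[2:]:
            t.harvested = True  # 2 remain
        p = params_with(lambdas=(0.5, 0.5, 0.5, 0.5), lookahead_n=5)
        got = fk.lookahead_cost(p, START_INDEX, 0, d, hand_mm)
        want = naive_lookahead_cost(p, START_INDEX, 0, d, hand_mm)
        assert got == pytest.approx(want)

    @pytest.mark.parametrize("depth", [1, 2, 3, 4, 5])
    def test_oracle_equivalence_random_instances(self, depth, hand_mm):
        rng = np.random.default_rng(depth)
        for _ in range(10):
            d = fk.generate_display("small_high", int(rng.integers(2**31)))
            n_remaining = int(rng.integers(2, 9))
            keep = rng.choice(15, size=n_remaining, replace=False)
            for t in d.targets:
                t.harvested = t.id not in keep
            lam = tuple(rng.uniform(0, 1, size=depth - 1))
            p = params_with(lambdas=lam, lookahead_n=depth,
                            gamma=float(rng.uniform(0.5, 2.0)))
            origin = int(rng.choice(np.append(keep, START_INDEX)))
            candidate = int(rng.choice(keep))
            if origin == candidate:
                origin = START_INDEX
            got = fk.lookahead_cost(p, origin, candidate, d, hand_mm)
            want = naive_lookahead_cost(p, origin, candidate, d, hand_mm)
            assert got == pytest.approx(want, rel=1e-10)


class TestPermTable:
    def test_counts_and_grouping(self):
        t = _perm_table(5, 3)
        assert t.shape == (60, 3)
        # grouped by first element, equal group sizes
        assert np.array_equal(t[:12, 0], np.zeros(12, dtype=t.dtype))
        rows = {tuple(r) for r in t.tolist()}
        assert len(rows) == 60


class TestChoiceProbabilities:
    def test_beta_zero_uniform_over_14(self, hand_mm):
        d = fk.generate_display("value", 3)
        d.targets[4].harvested = True
        p = params_with(beta=0.0)
        ids, probs = fk.choice_probabilities(p, 4, d, hand_mm)
        assert len(ids) == 14
        assert np.allclose(probs, 1 / 14)
        assert probs[0] == pytest.approx(0.0714, abs=5e-4)

    def test_two_costs_direct_softmax(self):
        probs = softmax_probabilities(1.0, np.array([1.0, 2.0]))
        assert probs == pytest.approx([0.7311, 0.2689], abs=1e-4)

    def test_large_beta_argmin_cost(self, hand_mm):
        d = fk.generate_display("small_low", 6)
        p = params_with(beta=1e6)
        ids, probs = fk.choice_probabilities(p, START_INDEX, d, hand_mm)
        ctx = DisplayContext(d, hand_mm)
        costs = ctx.cost_matrix(p)[START_INDEX, ids]
        assert probs[np.argmin(costs)] == pytest.approx(1.0)

    def test_probabilities_ordered_inverse_to_cost(self, hand_mm):
        d = fk.generate_display("small_high", 10)
        p = params_with(beta=0.02)
        ids, probs = fk.choice_probabilities(p, START_INDEX, d, hand_mm)
        ctx = DisplayContext(d, hand_mm)
        costs = ctx.cost_matrix(p)[START_INDEX, ids]
        assert np.array_equal(np.argsort(costs), np.argsort(-probs))

    def test_sums_to_one(self, hand_mm):
        d = fk.generate_display("size", 17)
        p = params_with(beta=0.1, gamma=0.7)
        _, probs = fk.choice_probabilities(p, START_INDEX, d, hand_mm)
        assert probs.sum() == pytest.approx(1.0)

    def test_empty_candidates_rejected(self, hand_mm):
        d = fk.generate_display("size", 0)
        for t in d.targets:
            t.harvested = True
        with pytest.raises(NoCandidatesError):
            fk.choice_probabilities(params_with(), START_INDEX, d, hand_mm)

    def test_monotone_in_distance(self, hand_mm):
        # moving a candidate farther (w1>0, reward rate off) lowers its P
        p = params_with(include_reward_rate=False, include_size=False,
                        beta=0.5, w1=100.0)
        d = fk.generate_display("value", 0, jitter=0.0)
        _, probs0 = fk.choice_probabilities(p, START_INDEX, d, hand_mm)
        far = fk.generate_display("value", 0, jitter=0.0)
        x, y = far.targets[2].position
        far.targets[2].position = (x, y + 0.05)
        _, probs1 = fk.choice_probabilities(p, START_INDEX, far, hand_mm)
        assert probs1[2] < probs0[2]


class TestSessionLogLikelihood:
    def test_beta_zero_counts_remaining(self, hand_mm, gen_params):
        agent = fk.AgentSpec(kind="uniform", effector="hand", time_budget=10.0)
        d = fk.generate_display("value", 21)
        records, _ = fk.simulate_trial(agent, d, hand_mm, 0)
        records = records[:8]
        session = fk.SessionData("hand", hand_mm, [(d, records)])
        ll, n = fk.session_log_likelihood(params_with(beta=0.0), session)
        expected = -sum(math.log(m) for m in range(14, 7, -1))
        assert n == 7
        assert ll == pytest.approx(expected)
        assert ll == pytest.approx(-16.666, abs=5e-3)

    def test_single_scored_choice_two_candidates(self, hand_mm):
        # constrained trial with three high-value targets: after harvest 1
        # exactly two legal candidates remain; beta=0 -> log(1/2)
        d = fk.generate_display("value", 5)
        high = [t.id for t in d.targets if t.value == 15]
        for t in d.targets:
            if t.value == 15 and t.id not in high[:3]:
                t.value = 12
        d.reset_harvested()
        recs = [
            fk.HarvestRecord(d.trial_id, 1, high[0], START_INDEX, 0.3),
            fk.HarvestRecord(d.trial_id, 2, high[1], high[0], 0.3),
        ]
        session = fk.SessionData("hand", hand_mm, [(d, recs)], constrained=True)
        ll, n = fk.session_log_likelihood(params_with(beta=0.0), session)
        assert n == 1
        assert ll == pytest.approx(math.log(0.5))

    def test_shift_invariance_via_size_term(self, hand_mm, small_session):
        # value-condition trials have constant radius, so w2 shifts every
        # candidate cost equally and cannot change the likelihood
        trials = [
            (d, r) for d, r in small_session.trials
            if d.condition.name == "value"
        ]
        session = fk.SessionData("hand", hand_mm, trials)
        a = fk.session_log_likelihood(params_with(w2=0.0), session)
        b = fk.session_log_likelihood(params_with(w2=12345.0), session)
        assert a.log_likelihood == pytest.approx(b.log_likelihood)
        assert a.n_choices == b.n_choices

    def test_chosen_must_be_unharvested(self, hand_mm):
        d = fk.generate_display("value", 1)
        recs = [
            fk.HarvestRecord(0, 1, 3, START_INDEX, 0.3),
            fk.HarvestRecord(0, 2, 3, 3, 0.3),
        ]
        session = fk.SessionData("hand", hand_mm, [(d, recs)])
        with pytest.raises(LikelihoodError):
            fk.session_log_likelihood(params_with(), session)

    @pytest.mark.parametrize("depth,lam", [(1, ()), (2, (0.4,)), (3, (0.5, 0.2))])
    def test_cached_equals_loop(self, small_session, depth, lam):
        p = params_with(lambdas=lam, lookahead_n=depth, gamma=1.2)
        lik = SessionLikelihood(small_session, depth)
        loop = fk.session_log_likelihood(p, small_session)
        assert lik(p) == pytest.approx(loop.log_likelihood)
        assert lik.n_choices == loop.n_choices

    def test_continuity_finite_differences(self, small_session):
        # second differences stay small relative to first differences
        def ll(**kw):
            return fk.session_log_likelihood(params_with(**kw),
                                             small_session).log_likelihood

        for name, val, h in [("beta", 0.05, 1e-5), ("w1", 500.0, 1e-2),
                             ("gamma", 1.0, 1e-5), ("w2", 1000.0, 1e-2)]:
            f0, fp, fm = ll(**{name: val}), ll(**{name: val + h}), ll(**{name: val - h})
            first = (fp - fm) / (2 * h)
            second = (fp - 2 * f0 + fm) / h**2
            assert np.isfinite([f0, fp, fm]).all()
            assert abs(fp - f0) < max(1.0, abs(first) * h * 10)
            assert np.isfinite(second)


class TestParamsValidation:
    def test_lambda_length_must_match_depth(self):
        with pytest.raises(ValueError):
            fk.ChoiceModelParams(lambdas=(0.5,), lookahead_n=3)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            fk.ChoiceModelParams(beta=-0.1)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            fk.ChoiceModelParams(gamma=0.0)

    @given(beta=st.floats(0.001, 1.0), w2=st.floats(-100, 100))
    @settings(max_examples=20, deadline=None)
    def test_softmax_normalizes(self, beta, w2):
        costs = np.array([1.0, -3.0, w2, 7.5])
        probs = softmax_probabilities(beta, costs)
        assert probs.sum() == pytest.approx(1.0)
        assert np.all(probs > 0)
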