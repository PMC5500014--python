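import numpy as np
import pytest

import foragekit as fk


@pytest.fixture(scope="session")
def hand_mm():
    return fk.default_movement_model("hand")


@pytest.fixture(scope="session")
def eye_mm():
    return fk.default_movement_model("eye")


@pytest.fixture(scope="session")
def gen_params():
    """Reference 1-ahead generator parameters."""
    return fk.ChoiceModelParams(beta=0.05, w1=500.0, gamma=1.0, w2=1000.0,
                                lookahead_n=1)


@pytest.fixture(scope="session")
def small_session(hand_mm, gen_params):
    """Free-task model-agent session, 5 trials per condition (20 trials)."""
    agent = fk.AgentSpec(kind="model", params=gen_params, effector="hand",
                         time_noise_sd=0.05)
    return fk.generate_session(agent, hand_mm, trials_per_condition=5, seed=42)


@pytest.fixture(scope="session")
def medium_session(hand_mm, gen_params):
    """Free-task model-agent session, 25 trials per condition (100 trials)."""
    agent = fk.AgentSpec(kind="model", params=gen_params, effector="hand",
                         time_noise_sd=0.05)
    return fk.generate_session(agent, hand_mm, trials_per_condition=25, seed=7)


@pytest.fixture(scope="session")
def constrained_session(hand_mm, gen_params):
    """Constrained-task session (value order enforced), 3 x 10 trials."""
    agent = fk.AgentSpec(kind="model", params=gen_params, effector="hand",
                         time_noise_sd=0.05, constrained=True)
    return fk.generate_session(agent, hand_mm, trials_per_condition=10, seed=9)


def naive_step_cost(params, origin, candidate, display, mm):
    """Independent scalar cost: recomputed from raw geometry, no package
    cost code."""
    import math

    tgt = display.targets[candidate]
    if origin == fk.environment.START_INDEX:
        ox, oy = display.start_position
    else:
        ox, oy = display.targets[origin].position
    d = math.hypot(tgt.position[0] - ox, tgt.position[1] - oy)
    slope = mm.slope_by_radius[tgt.radius]
    intercept = mm.intercept_by_radius[tgt.radius]
    c = 0.0
    if params.include_reward_rate:
        c -= tgt.value / (intercept + slope * d)
    if params.include_distance:
        c += params.w1 * d**params.gamma
    if params.include_size:
        c -= params.w2 * tgt.radius
    return c


def naive_lookahead_cost(params, origin, candidate, display, mm):
    """Brute-force recursive enumeration of the look-ahead cost."""
    remaining = frozenset(
        t.id for t in display.targets if not t.harvested and t.id != candidate
    )
    horizon = min(params.lookahead_n, len(remaining) + 1)
    lambdas = params.lambdas[: horizon - 1]

    def best_tail(cur, rem, ws):
        if not ws:
            return 0.0
        return min(
            ws[0] * naive_step_cost(params, cur, k, display, mm)
            + best_tail(k, rem - {k}, ws[1:])
            for k in rem
        )

    return naive_step_cost(params, origin, candidate, display, mm) + best_tail(
        candidate, remaining, lambdas
    )
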