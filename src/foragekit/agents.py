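"""Synthetic-session engine: simulated agents and the rate-maximizing planner.

Agents harvest targets under a fixed trial clock (default 3.25 s).  The
``model`` agent samples from the cost/softmax choice model; ``uniform``
picks equiprobably among legal targets; ``greedy`` maximizes immediate
reward rate; ``planner`` re-plans a rate-maximizing sequence of up to five
targets at every harvest and commits only the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .choice import (
    ChoiceModelParams,
    DisplayContext,
    HarvestRecord,
    SessionData,
    _perm_table,
    lookahead_costs,
    softmax_probabilities,
)
from .environment import (
    CONSTRAINED_CONDITIONS,
    Display,
    FREE_CONDITIONS,
    N_TARGETS,
    START_INDEX,
    generate_display,
    legal_next_targets,
)
from .exceptions import NoCandidatesError
from .movement import MovementTimeModel, default_movement_model, sample_duration

AGENT_KINDS = ("model", "uniform", "greedy", "planner")
DEFAULT_TIME_BUDGET = 3.25  # s
PLANNER_DEPTH = 5


@dataclass(frozen=True)
class AgentSpec:
    """Configuration of one simulated agent."""

    kind: str = "model"
    params: ChoiceModelParams = field(default_factory=ChoiceModelParams)
    effector: str = "hand"
    time_budget: float = DEFAULT_TIME_BUDGET
    time_noise_sd: float = 0.0
    constrained: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}; expected {AGENT_KINDS}")
        if self.time_budget <= 0:
            raise ValueError("time_budget must be > 0")
        if self.time_noise_sd < 0:
            raise ValueError("time_noise_sd must be >= 0")


@dataclass
class PlannerChoice:
    """One planner decision: the best (possibly truncated) sequence found."""

    chosen_sequence: tuple[int, ...]
    predicted_points: float
    predicted_time: float
    rate: float

    @property
    def empty(self) -> bool:
        return not self.chosen_sequence


def optimal_planner_choice(
    display: Display,
    movement_model: MovementTimeModel,
    remaining_time: float,
    depth: int = PLANNER_DEPTH,
    origin: int = START_INDEX,
) -> PlannerChoice:
    """Rate-maximizing sequence of up to ``depth`` unharvested targets.

    Every ordered sequence of unharvested targets up to length ``depth`` is
    enumerated, truncated at the longest prefix whose predicted total time
    fits within ``remaining_time``, and scored by points/time of that
    prefix.  Ties are broken by fewer targets, then by lowest first target
    id (then lexicographically), making the choice deterministic.  If no
    single harvest fits, an empty sentinel choice is returned.
    """
    if remaining_time <= 0:
        raise ValueError("remaining_time must be > 0")
    rem = np.array(
        sorted(t.id for t in display.targets if not t.harvested), dtype=np.intp
    )
    if rem.size == 0:
        raise NoCandidatesError("no unharvested target remains")
    ctx = DisplayContext(display, movement_model)
    m = rem.size
    length = min(depth, m)
    perms = _perm_table(m, length)
    seq = rem[perms]  # (n_perms, L)
    frm = np.concatenate(
        [np.full((seq.shape[0], 1), origin, dtype=np.intp), seq[:, :-1]], axis=1
    )
    leg_times = ctx.times[frm, seq]
    cum_time = np.cumsum(leg_times, axis=1)
    cum_pts = np.cumsum(ctx.values[seq], axis=1)
    fits = cum_time <= remaining_time
    prefix_len = fits.sum(axis=1)  # legs of each sequence that fit
    ok = prefix_len > 0
    if not ok.any():
        return PlannerChoice((), 0.0, 0.0, 0.0)
    idx = np.flatnonzero(ok)
    last = prefix_len[idx] - 1
    pts = cum_pts[idx, last]
    times = cum_time[idx, last]
    rates = pts / times
    # lexicographic tie-break: highest rate, then shortest prefix, then ids
    order = np.lexsort(
        tuple(seq[idx, c] for c in range(length - 1, -1, -1))
        + (prefix_len[idx], -rates)
    )
    win = idx[order[0]]
    k = int(prefix_len[win])
    return PlannerChoice(
        chosen_sequence=tuple(int(t) for t in seq[win, :k]),
        predicted_points=float(cum_pts[win, k - 1]),
        predicted_time=float(cum_time[win, k - 1]),
        rate=float(cum_pts[win, k - 1] / cum_time[win, k - 1]),
    )


def _choose(
    agent: AgentSpec,
    display: Display,
    ctx: DisplayContext,
    origin: int,
    remaining_time: float,
    rng: np.random.Generator,
) -> int | None:
    legal = np.array(sorted(legal_next_targets(display, agent.constrained)),
                     dtype=np.intp)
    if legal.size == 0:
        return None
    if agent.kind == "uniform":
        return int(rng.choice(legal))
    if agent.kind == "greedy":
        rates = ctx.rates[origin, legal]
        return int(legal[int(np.argmax(rates))])
    if agent.kind == "planner":
        if remaining_time <= 0:
            return None
        choice = optimal_planner_choice(
            display, ctx.movement_model, remaining_time, PLANNER_DEPTH, origin
        )
        return None if choice.empty else choice.chosen_sequence[0]
    # model agent
    rem = np.array(
        sorted(t.id for t in display.targets if not t.harvested), dtype=np.intp
    )
    costs = lookahead_costs(agent.params, origin, rem, ctx.cost_matrix(agent.params))
    mask = np.isin(rem, legal)
    probs = softmax_probabilities(agent.params.beta, costs[mask])
    return int(rng.choice(legal, p=probs))


def simulate_trial(
    agent: AgentSpec,
    display: Display,
    movement_model: MovementTimeModel,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[HarvestRecord], int]:
    """Simulate one trial; returns the harvest records and total points.

    A harvest counts only if its completion time fits within the time
    budget; the overrunning harvest is discarded and the trial ends.
    ``display`` must carry no harvested flags; it is left unmodified.
    """
    if display.harvested_ids():
        raise ValueError("simulate_trial requires a fresh display")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    work = display.copy()
    ctx = DisplayContext(work, movement_model)
    records: list[HarvestRecord] = []
    points = 0
    origin = START_INDEX
    clock = 0.0
    while True:
        chosen = _choose(agent, work, ctx, origin, agent.time_budget - clock, rng)
        if chosen is None:
            break
        dt = sample_duration(
            movement_model,
            float(ctx.distances[origin, chosen]),
            work.targets[chosen].radius,
            agent.time_noise_sd,
            rng,
        )
        if clock + dt > agent.time_budget:
            break
        clock += dt
        records.append(
            HarvestRecord(
                trial_id=display.trial_id,
                harvest_index=len(records) + 1,
                chosen_target_id=chosen,
                origin_target_id=origin,
                inter_harvest_time=dt,
            )
        )
        points += work.targets[chosen].value
        work.targets[chosen].harvested = True
        origin = chosen
    return records, points


def generate_session(
    agent: AgentSpec,
    movement_model: MovementTimeModel | None = None,
    conditions: Sequence[str] | None = None,
    trials_per_condition: int = 50,
    seed: int | None = None,
) -> SessionData:
    """Simulate a full session: ``trials_per_condition`` trials per condition.

    Free task defaults to the four conditions (200 trials); the
    constrained task omits the size condition (150 trials).  Fully
    reproducible from ``seed`` (falls back to ``agent.seed``).
    """
    if movement_model is None:
        movement_model = default_movement_model(agent.effector)
    if conditions is None:
        conditions = CONSTRAINED_CONDITIONS if agent.constrained else FREE_CONDITIONS
    if seed is None:
        seed = agent.seed
    root = np.random.SeedSequence(seed)
    display_rng, agent_rng = (np.random.default_rng(s) for s in root.spawn(2))
    trials = []
    trial_id = 0
    for cond in conditions:
        for _ in range(trials_per_condition):
            display = generate_display(cond, display_rng, trial_id=trial_id)
            records, _ = simulate_trial(agent, display, movement_model, agent_rng)
            trials.append((display, records))
            trial_id += 1
    return SessionData(
        effector=agent.effector,
        movement_model=movement_model,
        trials=trials,
        constrained=agent.constrained,
    )


def efficiency_ratios(
    session: SessionData,
    planner_session: SessionData,
) -> tuple[float, float, int]:
    """Mean per-trial actual/planner ratios of points and harvest counts.

    Both sessions must be simulated on the same displays (matched by
    trial).  Trials where the planner scores zero are excluded; the count
    of exclusions is returned as the third element.
    """
    if session.n_trials() != planner_session.n_trials():
        raise ValueError("sessions must have the same number of trials")
    pt_ratios, ct_ratios = [], []
    excluded = 0
    for (disp_a, recs_a), (disp_p, recs_p) in zip(
        session.trials, planner_session.trials
    ):
        values = disp_p.values()
        planner_pts = sum(values[r.chosen_target_id] for r in recs_p)
        if planner_pts == 0:
            excluded += 1
            continue
        actual_values = disp_a.values()
        actual_pts = sum(actual_values[r.chosen_target_id] for r in recs_a)
        pt_ratios.append(actual_pts / planner_pts)
        ct_ratios.append(len(recs_a) / len(recs_p))
    if not pt_ratios:
        raise ValueError("no trial with nonzero planner score")
    return float(np.mean(pt_ratios)), float(np.mean(ct_ratios)), excluded


def planner_session_for(
    session: SessionData,
    movement_model: MovementTimeModel | None = None,
    time_budget: float = DEFAULT_TIME_BUDGET,
) -> SessionData:
    """Re-run the optimal planner (noiseless timing) on a session's displays."""
    mm = movement_model or session.movement_model
    agent = AgentSpec(kind="planner", effector=session.effector,
                      time_budget=time_budget, time_noise_sd=0.0,
                      constrained=session.constrained)
    trials = []
    for display, _ in session.trials:
        fresh = display.copy()
        fresh.reset_harvested()
        records, _ = simulate_trial(agent, fresh, mm, np.random.default_rng(0))
        trials.append((fresh, records))
    return SessionData(session.effector, mm, trials, session.constrained)
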