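"""Cost/softmax choice model with N-step look-ahead.

The immediate cost of moving from target ``i`` to candidate ``j`` is

    c_ij = -v_j / t_ij  +  w1 * d_ij**gamma  -  w2 * s_j

(reward-rate, distance-penalty and size-bonus terms individually
switchable).  An n-step look-ahead scores candidate ``j`` by the minimum,
over all ordered continuations of distinct unharvested targets, of the
immediate cost plus discounted future step costs; choice probabilities are
a softmax with precision ``beta`` over the legal candidates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np

from .environment import (
    Display,
    N_TARGETS,
    START_INDEX,
    distance_matrix,
    legal_next_targets,
)
from .exceptions import (
    LikelihoodError,
    NoCandidatesError,
    NonpositiveTimeError,
)
from .movement import MovementTimeModel, predicted_time_matrix, predict_time

MAX_LOOKAHEAD = 5


@dataclass(frozen=True)
class ChoiceModelParams:
    """Free parameters and structure flags of the choice model."""

    beta: float = 0.05
    w1: float = 500.0
    gamma: float = 1.0
    w2: float = 1000.0
    lambdas: tuple[float, ...] = ()
    lookahead_n: int = 1
    include_reward_rate: bool = True
    include_distance: bool = True
    include_size: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.lookahead_n <= MAX_LOOKAHEAD:
            raise ValueError(f"lookahead_n must be in 1..{MAX_LOOKAHEAD}")
        if len(self.lambdas) != self.lookahead_n - 1:
            raise ValueError(
                f"need {self.lookahead_n - 1} lambda weights for "
                f"lookahead_n={self.lookahead_n}, got {len(self.lambdas)}"
            )
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    @property
    def submodel(self) -> str:
        if not self.include_reward_rate:
            return "no_reward_rate"
        if not self.include_distance:
            return "no_distance"
        if not self.include_size:
            return "no_size"
        return "full"

    def step_weights(self, horizon: int | None = None) -> np.ndarray:
        """(1, lambda_1, ..) truncated to ``horizon`` steps."""
        w = np.concatenate(([1.0], np.asarray(self.lambdas, dtype=float)))
        return w if horizon is None else w[:horizon]


@dataclass
class HarvestRecord:
    """One successful harvest within a trial."""

    trial_id: int
    harvest_index: int  # 1-based
    chosen_target_id: int
    origin_target_id: int  # previous harvest, or START_INDEX for the start
    inter_harvest_time: float  # s


@dataclass
class SessionData:
    """All trials and harvest sequences for one (simulated) participant."""

    effector: str
    movement_model: MovementTimeModel
    trials: list[tuple[Display, list[HarvestRecord]]]
    constrained: bool = False

    def n_trials(self) -> int:
        return len(self.trials)


class ChoiceProbabilities(NamedTuple):
    ids: np.ndarray  # legal candidate ids
    probabilities: np.ndarray  # same order, sums to 1


class LikelihoodResult(NamedTuple):
    log_likelihood: float
    n_choices: int


# ---------------------------------------------------------------------------
# Per-display cached geometry/timing
# ---------------------------------------------------------------------------


@dataclass
class DisplayContext:
    """Distance, predicted-time and reward-rate matrices for one display.

    Rows index the origin (0-14 targets, 15 = start); columns index the
    destination target.
    """

    display: Display
    movement_model: MovementTimeModel
    distances: np.ndarray = field(init=False)  # (16, 15)
    times: np.ndarray = field(init=False)  # (16, 15)
    rates: np.ndarray = field(init=False)  # (16, 15)
    radii: np.ndarray = field(init=False)  # (15,)
    values: np.ndarray = field(init=False)  # (15,)

    def __post_init__(self) -> None:
        full = distance_matrix(self.display)
        self.distances = full[:, :N_TARGETS]
        self.radii = self.display.radii()
        self.values = self.display.values()
        self.times = predicted_time_matrix(
            self.movement_model, self.distances, self.radii
        )
        if np.any(self.times[self.distances > 0] <= 0):
            raise NonpositiveTimeError(
                "movement-time model predicts nonpositive durations"
            )
        with np.errstate(divide="ignore"):
            self.rates = self.values / self.times

    def cost_matrix(self, params: ChoiceModelParams) -> np.ndarray:
        """(16, 15) immediate step costs under ``params``."""
        c = np.zeros_like(self.distances)
        if params.include_reward_rate:
            c -= self.rates
        if params.include_distance:
            c += params.w1 * self.distances**params.gamma
        if params.include_size:
            c -= params.w2 * self.radii
        return c


# ---------------------------------------------------------------------------
# Costs
# ---------------------------------------------------------------------------


def reward_rate(value: float, predicted_time: float) -> float:
    """Points per second: ``value / predicted_time``."""
    if predicted_time <= 0:
        raise NonpositiveTimeError(
            f"predicted time must be > 0, got {predicted_time}"
        )
    return float(value) / float(predicted_time)


def step_cost(
    params: ChoiceModelParams,
    origin: int,
    candidate: int,
    display: Display,
    movement_model: MovementTimeModel,
) -> float:
    """Immediate cost of harvesting ``candidate`` from ``origin``."""
    tgt = display.targets[candidate]
    pts = display.positions()
    opos = (
        np.asarray(display.start_position)
        if origin == START_INDEX
        else pts[origin]
    )
    d = float(np.hypot(*(pts[candidate] - opos)))
    c = 0.0
    if params.include_reward_rate:
        t = predict_time(movement_model, d, tgt.radius)
        c -= reward_rate(tgt.value, t)
    if params.include_distance:
        c += params.w1 * d**params.gamma
    if params.include_size:
        c -= params.w2 * tgt.radius
    return c


@lru_cache(maxsize=128)
def _perm_table(m: int, length: int) -> np.ndarray:
    """All ordered ``length``-tuples of distinct indices from ``range(m)``.

    Rows are in lexicographic order, hence grouped by first element with
    equal group sizes.
    """
    perms = np.fromiter(
        itertools.chain.from_iterable(itertools.permutations(range(m), length)),
        dtype=np.int8,
    )
    return perms.reshape(-1, length)


def lookahead_costs(
    params: ChoiceModelParams,
    origin: int,
    remaining: np.ndarray,
    cost_mat: np.ndarray,
) -> np.ndarray:
    """Look-ahead cost C_j for every id in ``remaining`` (same order).

    The horizon truncates to the number of remaining targets when fewer
    than ``lookahead_n`` remain.
    """
    rem = np.asarray(remaining, dtype=np.intp)
    m = rem.size
    horizon = min(params.lookahead_n, m)
    if horizon == 1:
        return cost_mat[origin, rem].astype(float, copy=True)
    perms = _perm_table(m, horizon)
    seq = rem[perms]  # (n_perms, horizon)
    frm = np.concatenate(
        [np.full((seq.shape[0], 1), origin, dtype=np.intp), seq[:, :-1]], axis=1
    )
    leg_costs = cost_mat[frm, seq]
    path = leg_costs @ params.step_weights(horizon)
    return path.reshape(m, -1).min(axis=1)


def lookahead_cost(
    params: ChoiceModelParams,
    origin: int,
    candidate: int,
    display: Display,
    movement_model: MovementTimeModel,
) -> float:
    """Look-ahead cost C_j of a single candidate on a display."""
    ctx = DisplayContext(display, movement_model)
    rem = np.array(
        sorted(t.id for t in display.targets if not t.harvested), dtype=np.intp
    )
    if candidate not in rem:
        raise ValueError(f"candidate {candidate} is harvested or unknown")
    costs = lookahead_costs(params, origin, rem, ctx.cost_matrix(params))
    return float(costs[rem == candidate][0])


# ---------------------------------------------------------------------------
# Softmax choice rule
# ---------------------------------------------------------------------------


def softmax_probabilities(beta: float, costs: np.ndarray) -> np.ndarray:
    """``exp(-beta*C_j) / sum`` with max-subtraction for stability."""
    z = -beta * np.asarray(costs, dtype=float)
    z -= z.max()
    ez = np.exp(z)
    return ez / ez.sum()


def choice_probabilities(
    params: ChoiceModelParams,
    origin: int,
    display: Display,
    movement_model: MovementTimeModel,
    constrained: bool = False,
) -> ChoiceProbabilities:
    """Softmax selection probabilities over the legal candidates.

    Look-ahead continuations range over all unharvested targets even when
    the candidate set is restricted by the constrained-task rule.
    """
    legal = legal_next_targets(display, constrained)
    if not legal:
        raise NoCandidatesError("no unharvested legal targets remain")
    ctx = DisplayContext(display, movement_model)
    rem = np.array(
        sorted(t.id for t in display.targets if not t.harvested), dtype=np.intp
    )
    costs = lookahead_costs(params, origin, rem, ctx.cost_matrix(params))
    mask = np.isin(rem, sorted(legal))
    ids = rem[mask]
    return ChoiceProbabilities(ids, softmax_probabilities(params.beta, costs[mask]))


# ---------------------------------------------------------------------------
# Session likelihood
# ---------------------------------------------------------------------------

FIRST_SCORED_HARVEST = 2
MAX_SCORED_HARVEST = 8


def _scored_points(
    session: SessionData,
    first_scored: int,
    max_harvest: int,
):
    """Yield (trial_index, origin, chosen, remaining_ids, legal_ids)."""
    constrained = session.constrained
    for t_idx, (display, records) in enumerate(session.trials):
        harvested: set[int] = set()
        last_index = 0
        for rec in records:
            if rec.harvest_index != last_index + 1:
                raise LikelihoodError(
                    f"trial {display.trial_id}: harvest indices not "
                    f"consecutive at index {rec.harvest_index}"
                )
            last_index = rec.harvest_index
            if rec.chosen_target_id in harvested:
                raise LikelihoodError(
                    f"trial {display.trial_id}: target "
                    f"{rec.chosen_target_id} harvested twice"
                )
            if first_scored <= rec.harvest_index <= max_harvest:
                remaining = np.array(
                    sorted(set(range(N_TARGETS)) - harvested), dtype=np.intp
                )
                if constrained:
                    values = display.values()
                    vmax = values[remaining].max()
                    legal = remaining[values[remaining] == vmax]
                else:
                    legal = remaining
                if rec.chosen_target_id not in legal:
                    raise LikelihoodError(
                        f"trial {display.trial_id}: chosen target "
                        f"{rec.chosen_target_id} is not a legal candidate"
                    )
                yield t_idx, rec.origin_target_id, rec.chosen_target_id, remaining, legal
            harvested.add(rec.chosen_target_id)


def session_log_likelihood(
    params: ChoiceModelParams,
    session: SessionData,
    first_scored: int = FIRST_SCORED_HARVEST,
    max_harvest: int = MAX_SCORED_HARVEST,
) -> LikelihoodResult:
    """Summed log probability of the chosen targets over harvests 2-8.

    The first harvest of each trial is never scored and harvests beyond
    ``max_harvest`` are ignored; trials from all conditions are pooled.
    Returns the log-likelihood and the number of scored choices.
    """
    contexts = [
        DisplayContext(display, session.movement_model)
        for display, _ in session.trials
    ]
    cost_mats = [ctx.cost_matrix(params) for ctx in contexts]
    ll = 0.0
    n = 0
    for t_idx, origin, chosen, remaining, legal in _scored_points(
        session, first_scored, max_harvest
    ):
        costs = lookahead_costs(params, origin, remaining, cost_mats[t_idx])
        mask = np.isin(remaining, legal)
        probs = softmax_probabilities(params.beta, costs[mask])
        idx = int(np.where(remaining[mask] == chosen)[0][0])
        p = probs[idx]
        if p <= 0:
            raise LikelihoodError(
                f"scored choice has probability 0 (trial index {t_idx})"
            )
        ll += float(np.log(p))
        n += 1
    return LikelihoodResult(ll, n)


class SessionLikelihood:
    """Precomputed, vectorized session log-likelihood for repeated evaluation.

    Builds flat leg-index arrays over every scored choice point once, so
    each parameter evaluation reduces to a handful of gathers and
    segmented reductions.  Falls back to per-point evaluation when the
    look-ahead horizon varies across points or the enumeration would
    exceed ``max_entries`` table entries.
    """

    def __init__(
        self,
        session: SessionData,
        lookahead_n: int,
        first_scored: int = FIRST_SCORED_HARVEST,
        max_harvest: int = MAX_SCORED_HARVEST,
        max_entries: int = 60_000_000,
    ) -> None:
        self.session = session
        self.lookahead_n = lookahead_n
        contexts = [
            DisplayContext(d, session.movement_model) for d, _ in session.trials
        ]
        n_trials = len(contexts)
        self._D = np.stack([c.distances for c in contexts]).reshape(n_trials, -1)
        self._R = np.stack([c.rates for c in contexts]).reshape(n_trials, -1)
        S = np.stack(
            [np.broadcast_to(c.radii, (N_TARGETS + 1, N_TARGETS)) for c in contexts]
        )
        self._S = S.reshape(n_trials, -1)
        self._D = self._D.ravel()
        self._R = self._R.ravel()
        self._S = self._S.ravel()

        self.points = list(_scored_points(session, first_scored, max_harvest))
        self.n_choices = len(self.points)

        horizons = {min(lookahead_n, p[3].size) for p in self.points}
        est_rows = sum(
            _n_perms(p[3].size, min(lookahead_n, p[3].size)) for p in self.points
        )
        self._cached = (
            len(horizons) <= 1
            and est_rows * lookahead_n <= max_entries
            and self.n_choices > 0
        )
        if self._cached:
            self._build_tables()

    # -- table construction ------------------------------------------------
    def _build_tables(self) -> None:
        stride = (N_TARGETS + 1) * N_TARGETS
        leg_blocks = []
        grp_starts = []  # start row of each (point, candidate) group
        pt_starts = []  # start index of each point in the candidate array
        chosen_pos = []  # position of the chosen candidate, candidate array
        row_cursor = 0
        cand_cursor = 0
        horizon = min(self.lookahead_n, min(p[3].size for p in self.points))
        self.horizon = horizon
        for t_idx, origin, chosen, remaining, legal in self.points:
            m = remaining.size
            perms = _perm_table(m, horizon)
            group = perms.shape[0] // m  # rows per first element
            if legal.size != m:
                first_ok = np.isin(remaining, legal)
                keep = np.repeat(first_ok, group)
                perms = perms[keep]
                cands = remaining[first_ok]
            else:
                cands = remaining
            seq = remaining[perms]
            frm = np.concatenate(
                [np.full((seq.shape[0], 1), origin, dtype=np.intp), seq[:, :-1]],
                axis=1,
            )
            flat = t_idx * stride + frm * N_TARGETS + seq
            leg_blocks.append(flat.astype(np.int64))
            n_cand = cands.size
            grp_starts.extend(row_cursor + np.arange(n_cand) * group)
            pt_starts.append(cand_cursor)
            chosen_pos.append(cand_cursor + int(np.where(cands == chosen)[0][0]))
            row_cursor += perms.shape[0]
            cand_cursor += n_cand
        self._legs = np.concatenate(leg_blocks, axis=0)
        self._grp_starts = np.asarray(grp_starts, dtype=np.intp)
        self._pt_starts = np.asarray(pt_starts, dtype=np.intp)
        counts = np.diff(np.append(self._pt_starts, cand_cursor))
        self._pt_counts = counts
        self._chosen_pos = np.asarray(chosen_pos, dtype=np.intp)

    # -- evaluation --------------------------------------------------------
    def _flat_costs(self, params: ChoiceModelParams) -> np.ndarray:
        c = np.zeros_like(self._D)
        if params.include_reward_rate:
            c -= self._R
        if params.include_distance:
            c += params.w1 * self._D**params.gamma
        if params.include_size:
            c -= params.w2 * self._S
        return c

    def __call__(self, params: ChoiceModelParams) -> float:
        if params.lookahead_n != self.lookahead_n:
            raise ValueError(
                f"cache built for lookahead_n={self.lookahead_n}, "
                f"got {params.lookahead_n}"
            )
        if not self._cached:
            return session_log_likelihood(params, self.session).log_likelihood
        cflat = self._flat_costs(params)
        leg_costs = cflat[self._legs]
        if self.horizon == 1:
            path = leg_costs[:, 0]
        else:
            path = leg_costs @ params.step_weights(self.horizon)
        C = np.minimum.reduceat(path, self._grp_starts)
        z = -params.beta * C
        mx = np.maximum.reduceat(z, self._pt_starts)
        ez = np.exp(z - np.repeat(mx, self._pt_counts))
        sums = np.add.reduceat(ez, self._pt_starts)
        ll = z[self._chosen_pos] - mx - np.log(sums)
        return float(ll.sum())


def _n_perms(m: int, length: int) -> int:
    out = 1
    for k in range(length):
        out *= m - k
    return out
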