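"""Diagnostic summaries: selection probabilities and ranks, tier
proportions over harvests, distance distributions, and constrained-task
path ranking."""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .agents import AgentSpec, simulate_trial
from .choice import (
    ChoiceModelParams,
    DisplayContext,
    SessionData,
    _scored_points,
    lookahead_costs,
    softmax_probabilities,
)
from .environment import N_TARGETS, START_INDEX
from .fitting import FitResult

FIRST_HARVEST = 2
LAST_HARVEST = 8


def chance_level(harvest_index: int) -> float:
    """Uniform-chooser probability 1/(16 - h) at harvest ``h``."""
    return 1.0 / (N_TARGETS + 1 - harvest_index)


# ---------------------------------------------------------------------------
# Model-vs-data selection diagnostics
# ---------------------------------------------------------------------------


def selection_diagnostics(
    session: SessionData,
    fitted: FitResult | ChoiceModelParams,
) -> pd.DataFrame:
    """Per-harvest agreement between model probabilities and actual choices.

    For every scored choice (harvests 2-8) the model's selection
    probabilities are recomputed; the output reports, per harvest index,
    the rate at which the top-probability target was taken, the mean
    probability assigned to the taken target, the mean gap to the top
    probability, the mean rank of the taken target (descending
    probability, ties broken by lower target id), and the chance level.
    """
    params = fitted.params if isinstance(fitted, FitResult) else fitted
    contexts = [
        DisplayContext(d, session.movement_model) for d, _ in session.trials
    ]
    cost_mats = [ctx.cost_matrix(params) for ctx in contexts]
    acc: dict[int, list[tuple[float, float, float, float]]] = {}
    harvest_of_point = []
    for display, records in session.trials:
        for rec in records:
            if FIRST_HARVEST <= rec.harvest_index <= LAST_HARVEST:
                harvest_of_point.append(rec.harvest_index)
    for h_idx, (t_idx, origin, chosen, remaining, legal) in zip(
        harvest_of_point,
        _scored_points(session, FIRST_HARVEST, LAST_HARVEST),
    ):
        costs = lookahead_costs(params, origin, remaining, cost_mats[t_idx])
        mask = np.isin(remaining, legal)
        ids = remaining[mask]
        probs = softmax_probabilities(params.beta, costs[mask])
        order = np.lexsort((ids, -probs))  # descending prob, id tiebreak
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, ids.size + 1)
        pos = int(np.where(ids == chosen)[0][0])
        top = float(probs.max())
        acc.setdefault(h_idx, []).append(
            (
                1.0 if ranks[pos] == 1 else 0.0,
                float(probs[pos]),
                top - float(probs[pos]),
                float(ranks[pos]),
            )
        )
    rows = []
    for h in range(FIRST_HARVEST, LAST_HARVEST + 1):
        pts = acc.get(h, [])
        if pts:
            arr = np.array(pts)
            rows.append(
                dict(
                    harvest=h,
                    n=len(pts),
                    top_hit_rate=arr[:, 0].mean(),
                    mean_taken_probability=arr[:, 1].mean(),
                    mean_gap_to_top=arr[:, 2].mean(),
                    mean_taken_rank=arr[:, 3].mean(),
                    chance=chance_level(h),
                )
            )
        else:
            rows.append(
                dict(harvest=h, n=0, top_hit_rate=np.nan,
                     mean_taken_probability=np.nan, mean_gap_to_top=np.nan,
                     mean_taken_rank=np.nan, chance=chance_level(h))
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tier proportions over harvests
# ---------------------------------------------------------------------------


def selection_proportions(
    sessions: SessionData | Iterable[SessionData],
) -> pd.DataFrame:
    """Proportion of chosen targets per tier, by condition and harvest 2-8.

    In the size condition the tier is the target radius (mm); in all other
    conditions it is the point value.  Proportions sum to one across tiers
    within each (condition, harvest) cell with at least one choice.
    """
    if isinstance(sessions, SessionData):
        sessions = [sessions]
    counts: dict[tuple[str, int, float], int] = {}
    tier_kind: dict[str, str] = {}
    for session in sessions:
        for display, records in session.trials:
            cname = display.condition.name
            by_size = cname == "size"
            tier_kind[cname] = "radius_mm" if by_size else "value"
            for rec in records:
                if not FIRST_HARVEST <= rec.harvest_index <= LAST_HARVEST:
                    continue
                tgt = display.targets[rec.chosen_target_id]
                tier = tgt.radius * 1000.0 if by_size else float(tgt.value)
                key = (cname, rec.harvest_index, tier)
                counts[key] = counts.get(key, 0) + 1
    rows = []
    conditions = sorted({k[0] for k in counts})
    for cname in conditions:
        tiers = sorted({k[2] for k in counts if k[0] == cname})
        for h in range(FIRST_HARVEST, LAST_HARVEST + 1):
            total = sum(counts.get((cname, h, t), 0) for t in tiers)
            for t in tiers:
                c = counts.get((cname, h, t), 0)
                rows.append(
                    dict(
                        condition=cname,
                        tier_by=tier_kind[cname],
                        harvest=h,
                        tier=t,
                        n=c,
                        proportion=c / total if total else np.nan,
                    )
                )
    return pd.DataFrame(rows)


def rollout_sessions(
    session: SessionData,
    params: ChoiceModelParams,
    n_rollouts: int = 25,
    seed: int | None = None,
    time_budget: float = 3.25,
    time_noise_sd: float = 0.0,
) -> list[SessionData]:
    """Monte-Carlo rollouts of a fitted model on a session's displays.

    Used to build model-predicted proportion and distance curves on the
    same stimuli the data were collected on.
    """
    rng = np.random.default_rng(seed)
    agent = AgentSpec(
        kind="model", params=params, effector=session.effector,
        time_budget=time_budget, time_noise_sd=time_noise_sd,
        constrained=session.constrained,
    )
    out = []
    for _ in range(n_rollouts):
        trials = []
        for display, _ in session.trials:
            fresh = display.copy()
            fresh.reset_harvested()
            records, _ = simulate_trial(agent, fresh, session.movement_model, rng)
            trials.append((fresh, records))
        out.append(
            SessionData(session.effector, session.movement_model, trials,
                        session.constrained)
        )
    return out


# ---------------------------------------------------------------------------
# Distance distribution
# ---------------------------------------------------------------------------


class DistanceHistogram(NamedTuple):
    counts: np.ndarray
    bin_edges: np.ndarray  # first edge at 0
    mode_bin_left: float | None  # left edge of the modal bin, None if empty


def distance_distribution(
    sessions: SessionData | Iterable[SessionData],
    bin_width: float = 0.015,
) -> DistanceHistogram:
    """Histogram of center-to-center distances between consecutive harvests.

    Only target-to-target legs are counted (the start-to-first leg is
    excluded); trials with fewer than two harvests contribute nothing.
    """
    if isinstance(sessions, SessionData):
        sessions = [sessions]
    dists = []
    for session in sessions:
        for display, records in session.trials:
            pos = display.positions()
            for rec in records:
                if rec.origin_target_id == START_INDEX:
                    continue
                d = pos[rec.chosen_target_id] - pos[rec.origin_target_id]
                dists.append(float(np.hypot(*d)))
    if not dists:
        return DistanceHistogram(np.array([], dtype=int), np.array([0.0]), None)
    arr = np.asarray(dists)
    n_bins = int(np.ceil(arr.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(arr, bins=edges)
    mode = float(edges[int(np.argmax(counts))])
    return DistanceHistogram(counts, edges, mode)


# ---------------------------------------------------------------------------
# Constrained-task path ranking
# ---------------------------------------------------------------------------


@dataclass
class PathRanking:
    """Ranking of one trial's first-five path among all 120 orders."""

    trial_id: int
    actual_length: float
    candidate_lengths: np.ndarray  # all 5! = 120 path lengths
    rank: int  # 1 = shortest; ties share the lower rank


@dataclass
class PathRankingSummary:
    rankings: list[PathRanking]
    n_excluded: int

    @property
    def proportion_rank1(self) -> float:
        return float(np.mean([r.rank == 1 for r in self.rankings]))

    def proportion_rank_at_most(self, k: int) -> float:
        return float(np.mean([r.rank <= k for r in self.rankings]))

    def mean_length_by_rank(self) -> np.ndarray:
        """Mean candidate path length at each rank (sorted), over trials."""
        stacked = np.stack([np.sort(r.candidate_lengths) for r in self.rankings])
        return stacked.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(trial_id=r.trial_id, actual_length=r.actual_length,
                     rank=r.rank)
                for r in self.rankings
            ]
        )


def path_lengths_through(
    positions: np.ndarray,
    start: np.ndarray | None,
    orders: Sequence[Sequence[int]],
) -> np.ndarray:
    """Total center-to-center length of each ordering of row indices."""
    out = np.empty(len(orders))
    for i, order in enumerate(orders):
        pts = positions[list(order)]
        legs = np.hypot(*(np.diff(pts, axis=0).T))
        total = float(legs.sum())
        if start is not None:
            total += float(np.hypot(*(pts[0] - start)))
        out[i] = total
    return out


def path_ranking(
    session: SessionData,
    include_start_leg: bool = True,
) -> PathRankingSummary:
    """Rank each constrained trial's first-five harvest path by length.

    All 120 orderings of the five highest-value targets are enumerated and
    summed (optionally including the start-to-first leg); the actual order
    receives rank 1 + (number of strictly shorter candidates).  Trials
    whose first five harvests are not exactly the five high-value targets
    are excluded and counted.
    """
    rankings = []
    excluded = 0
    for display, records in session.trials:
        values = display.values()
        vmax = values.max()
        high_ids = set(np.flatnonzero(values == vmax).tolist())
        first_five = [r.chosen_target_id for r in records[:5]]
        if len(high_ids) != 5 or set(first_five) != high_ids:
            excluded += 1
            continue
        pos = display.positions()
        start = np.asarray(display.start_position) if include_start_leg else None
        orders = list(itertools.permutations(sorted(high_ids)))
        lengths = path_lengths_through(pos, start, orders)
        actual = path_lengths_through(pos, start, [first_five])[0]
        rank = 1 + int(np.sum(lengths < actual))
        rankings.append(
            PathRanking(
                trial_id=display.trial_id,
                actual_length=float(actual),
                candidate_lengths=lengths,
                rank=rank,
            )
        )
    return PathRankingSummary(rankings, excluded)
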