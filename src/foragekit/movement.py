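"""Inter-harvest movement time as a linear function of distance, per radius tier.

Movement duration between successive harvests is modeled as
``intercept + slope * distance`` with separate ordinary-least-squares
coefficients for each target radius tier and effector.  Task-level mean
coefficients (hand: 1.0 s/m slope, 0.2 s intercept; eye: 0.9 s/m, 0.3 s)
are provided as simulation defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .environment import RADIUS_TIERS
from .exceptions import MovementTimeFitError, UnknownRadiusTierError

#: Floor applied to simulated noisy inter-harvest durations (s).
MIN_DURATION = 0.05

_DEFAULT_COEFS = {"hand": (1.0, 0.2), "eye": (0.9, 0.3)}


def canonical_radius(radius: float, tol: float = 1e-9) -> float:
    """Snap ``radius`` to a known tier, or raise :class:`UnknownRadiusTierError`."""
    for tier in RADIUS_TIERS:
        if abs(radius - tier) <= tol:
            return tier
    raise UnknownRadiusTierError(
        f"radius {radius!r} m does not match any tier in {RADIUS_TIERS}"
    )


@dataclass
class MovementTimeModel:
    """Per-radius linear time-vs-distance coefficients for one effector."""

    effector: str
    slope_by_radius: dict[float, float]  # s/m
    intercept_by_radius: dict[float, float]  # s
    resid_sd_by_radius: dict[float, float] = field(default_factory=dict)

    def predict(self, distance: float, radius: float) -> float:
        return predict_time(self, distance, radius)

    def coefficients(self, radius: float) -> tuple[float, float]:
        """(slope, intercept) for the tier matching ``radius``."""
        tier = canonical_radius(radius)
        try:
            return self.slope_by_radius[tier], self.intercept_by_radius[tier]
        except KeyError:
            raise UnknownRadiusTierError(
                f"no coefficients fitted for radius tier {tier} m"
            ) from None


def default_movement_model(effector: str) -> MovementTimeModel:
    """Task-level mean coefficients applied to every radius tier.

    Per-tier coefficients are not separately published, so simulations
    default to the task-level means for all tiers.
    """
    try:
        slope, intercept = _DEFAULT_COEFS[effector]
    except KeyError:
        raise ValueError(f"unknown effector {effector!r}; expected 'hand' or 'eye'")
    return MovementTimeModel(
        effector=effector,
        slope_by_radius={r: slope for r in RADIUS_TIERS},
        intercept_by_radius={r: intercept for r in RADIUS_TIERS},
        resid_sd_by_radius={r: 0.0 for r in RADIUS_TIERS},
    )


def fit_movement_time(
    harvest_records: Iterable[tuple[float, float, float]],
    effector: str = "hand",
) -> MovementTimeModel:
    """OLS fit of duration on distance, separately per radius tier.

    Parameters
    ----------
    harvest_records
        Iterable of ``(distance_m, duration_s, target_radius_m)`` triples.
    effector
        ``"hand"`` or ``"eye"`` (label only; does not change the fit).

    Raises
    ------
    MovementTimeFitError
        If any observed tier has fewer than two points or zero distance
        variance; the message names the offending tier.
    """
    by_tier: dict[float, list[tuple[float, float]]] = {}
    for dist, dur, radius in harvest_records:
        tier = canonical_radius(radius)
        by_tier.setdefault(tier, []).append((float(dist), float(dur)))
    if not by_tier:
        raise MovementTimeFitError("no harvest records supplied")

    slopes: dict[float, float] = {}
    intercepts: dict[float, float] = {}
    resid_sd: dict[float, float] = {}
    for tier, pairs in sorted(by_tier.items()):
        d = np.array([p[0] for p in pairs])
        t = np.array([p[1] for p in pairs])
        if len(pairs) < 2:
            raise MovementTimeFitError(
                f"radius tier {tier} m has {len(pairs)} record(s); need >= 2"
            )
        if np.ptp(d) == 0.0:
            raise MovementTimeFitError(
                f"radius tier {tier} m has zero distance variance"
            )
        res = stats.linregress(d, t)
        slopes[tier] = float(res.slope)
        intercepts[tier] = float(res.intercept)
        resid = t - (res.intercept + res.slope * d)
        dof = max(len(pairs) - 2, 1)
        resid_sd[tier] = float(np.sqrt(np.sum(resid**2) / dof))
    return MovementTimeModel(
        effector=effector,
        slope_by_radius=slopes,
        intercept_by_radius=intercepts,
        resid_sd_by_radius=resid_sd,
    )


def predict_time(model: MovementTimeModel, distance: float, radius: float) -> float:
    """Predicted movement duration ``intercept + slope * distance`` (s)."""
    if distance < 0:
        raise ValueError(f"distance must be >= 0, got {distance}")
    slope, intercept = model.coefficients(radius)
    return intercept + slope * float(distance)


def predicted_time_matrix(
    model: MovementTimeModel,
    distances: np.ndarray,
    radii: Sequence[float],
) -> np.ndarray:
    """Vectorized :func:`predict_time` over a distance matrix.

    ``distances`` has destination targets along its last axis; ``radii``
    gives the destination radius per column.
    """
    slopes = np.array([model.coefficients(r)[0] for r in radii])
    intercepts = np.array([model.coefficients(r)[1] for r in radii])
    return intercepts + slopes * np.asarray(distances, dtype=float)


def harvest_movement_records(sessions) -> list[tuple[float, float, float]]:
    """Extract (distance, duration, radius) regression triples.

    Accepts one session or an iterable of sessions (e.g. a free-choice and
    a constrained session pooled for the hand fit).  The
    start-to-first-harvest leg is included; distances are between
    successive target centers (or the start position for the first leg).
    """
    if hasattr(sessions, "trials"):
        sessions = [sessions]
    out = []
    for display, records in (t for s in sessions for t in s.trials):
        pos = np.vstack([display.positions(), np.asarray(display.start_position)])
        for rec in records:
            d = pos[rec.chosen_target_id] - pos[rec.origin_target_id]
            out.append(
                (
                    float(np.hypot(*d)),
                    float(rec.inter_harvest_time),
                    display.targets[rec.chosen_target_id].radius,
                )
            )
    return out


def sample_duration(
    model: MovementTimeModel,
    distance: float,
    radius: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> float:
    """Simulated duration: prediction plus Gaussian noise, floored at 0.05 s."""
    base = predict_time(model, distance, radius)
    if noise_sd > 0:
        base += float(rng.normal(0.0, noise_sd))
    return max(base, MIN_DURATION)
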