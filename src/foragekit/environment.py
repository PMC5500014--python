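"""Task environment: targets, conditions, display generation, and geometry.

Coordinate convention: x rightward, y away from the participant, origin at
the start position, SI units (meters) throughout.  The display is a nominal
3-row by 5-column grid with 0.06 m spacing whose first row lies 0.06 m
beyond the start position; per-trial positions add independent uniform
jitter to each grid node.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import UnknownConditionError

#: Allowed target radii (m), small / medium / large.
RADIUS_TIERS = (0.005, 0.008, 0.011)
#: Allowed target point values, low / medium / high.
VALUE_TIERS = (10, 12, 15)

GRID_ROWS = 3
GRID_COLS = 5
GRID_SPACING = 0.06  # m, both axes
START_POSITION = (0.0, 0.0)
#: Default half-width of the per-axis uniform position jitter (m).
JITTER_AMPLITUDE = 0.011
N_TARGETS = GRID_ROWS * GRID_COLS
#: Row/column index used for the start position in distance matrices.
START_INDEX = N_TARGETS

_PAIRINGS = {
    # condition -> three (radius, value) pairings, five targets each
    "size": ((0.005, 12), (0.008, 12), (0.011, 12)),
    "value": ((0.008, 10), (0.008, 12), (0.008, 15)),
    "small_high": ((0.005, 15), (0.008, 12), (0.011, 10)),
    "small_low": ((0.005, 10), (0.008, 12), (0.011, 15)),
}

CONDITION_NAMES = tuple(_PAIRINGS)
#: Conditions run in the free-choice task.
FREE_CONDITIONS = CONDITION_NAMES
#: Conditions run in the constrained (value-ordered) task; size is omitted
#: because all of its targets share the same value.
CONSTRAINED_CONDITIONS = ("value", "small_high", "small_low")


@dataclass(frozen=True)
class Condition:
    """A size/value pairing scheme, five targets per pairing."""

    name: str
    pairings: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        if len(self.pairings) != 3:
            raise UnknownConditionError(
                f"condition {self.name!r} must define exactly 3 pairings"
            )


def condition(name: str | Condition) -> Condition:
    """Look up a :class:`Condition` by name.

    Raises
    ------
    UnknownConditionError
        If ``name`` is not one of ``size``, ``value``, ``small_high``,
        ``small_low``.
    """
    if isinstance(name, Condition):
        return name
    try:
        return Condition(name, _PAIRINGS[name])
    except KeyError:
        raise UnknownConditionError(
            f"unknown condition {name!r}; expected one of {CONDITION_NAMES}"
        ) from None


@dataclass
class TargetSpec:
    """One circular target on the display."""

    id: int
    position: tuple[float, float]  # m
    radius: float  # m, one of RADIUS_TIERS
    value: int  # points, one of VALUE_TIERS
    harvested: bool = False


@dataclass
class Display:
    """A 15-target trial layout."""

    targets: list[TargetSpec]
    condition: Condition
    start_position: tuple[float, float] = START_POSITION
    trial_id: int = 0

    def __post_init__(self) -> None:
        if len(self.targets) != N_TARGETS:
            raise ValueError(
                f"display for trial {self.trial_id} has {len(self.targets)} "
                f"targets; expected {N_TARGETS}"
            )

    # -- convenience views -------------------------------------------------
    def positions(self) -> np.ndarray:
        """(15, 2) target center coordinates in meters."""
        return np.array([t.position for t in self.targets], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([t.radius for t in self.targets], dtype=float)

    def values(self) -> np.ndarray:
        return np.array([t.value for t in self.targets], dtype=float)

    def harvested_ids(self) -> set[int]:
        return {t.id for t in self.targets if t.harvested}

    def reset_harvested(self) -> None:
        for t in self.targets:
            t.harvested = False

    def copy(self) -> "Display":
        return Display(
            targets=[replace(t) for t in self.targets],
            condition=self.condition,
            start_position=self.start_position,
            trial_id=self.trial_id,
        )


def grid_nodes() -> np.ndarray:
    """(15, 2) nominal grid node coordinates; id = row * 5 + column."""
    xs = (np.arange(GRID_COLS) - GRID_COLS // 2) * GRID_SPACING
    ys = (np.arange(GRID_ROWS) + 1) * GRID_SPACING
    nodes = [(x, y) for y in ys for x in xs]
    return np.array(nodes, dtype=float)


def generate_display(
    cond: str | Condition,
    rng_seed: int | np.random.Generator | None = None,
    *,
    jitter: float = JITTER_AMPLITUDE,
    trial_id: int = 0,
) -> Display:
    """Generate one randomized display.

    The fifteen size/value assignments (five per pairing) are permuted
    uniformly over the grid slots, and each target is offset from its grid
    node by independent per-axis uniform(-jitter, +jitter) draws.
    """
    cond = condition(cond)
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed

    labels = np.repeat(np.arange(3), N_TARGETS // 3)
    labels = rng.permutation(labels)
    offsets = rng.uniform(-jitter, jitter, size=(N_TARGETS, 2))
    nodes = grid_nodes()

    targets = []
    for i in range(N_TARGETS):
        radius, value = cond.pairings[labels[i]]
        pos = nodes[i] + offsets[i]
        targets.append(
            TargetSpec(id=i, position=(float(pos[0]), float(pos[1])),
                       radius=radius, value=value)
        )
    return Display(targets=targets, condition=cond, trial_id=trial_id)


def distance_matrix(display: Display) -> np.ndarray:
    """(16, 16) symmetric center-to-center distances in meters.

    Row/column :data:`START_INDEX` (= 15) is the start position.
    """
    pts = np.vstack([display.positions(), np.asarray(display.start_position)])
    diff = pts[:, None, :] - pts[None, :, :]
    return np.hypot(diff[..., 0], diff[..., 1])


def legal_next_targets(display: Display, constrained: bool = False) -> set[int]:
    """Ids that may legally be harvested next.

    Unconstrained: every non-harvested target.  Constrained: only the
    non-harvested targets of maximal remaining value (harvest in
    non-increasing value order).  All targets harvested yields an empty set.
    """
    remaining = [t for t in display.targets if not t.harvested]
    if not remaining:
        return set()
    if not constrained:
        return {t.id for t in remaining}
    vmax = max(t.value for t in remaining)
    return {t.id for t in remaining if t.value == vmax}


def all_orderings_count(n_targets: int = N_TARGETS) -> int:
    """Number of complete harvest orderings of ``n_targets`` targets."""
    import math

    return math.factorial(n_targets)
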