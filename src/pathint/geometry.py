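"""Triangle-completion task geometry.

The task takes place in a square tracked space (3.5 x 3.5 m by default) with
the origin at its centre and axes parallel to the walls.  Each trial is an
L-shaped outward path over three cone locations c1 -> c2 -> c3; the unguided
return leg c3 -> c1 is the assessed path-integration response.  Cone layouts
are generated pseudo-randomly under leg-length and turn-angle constraints, and
return paths that stray more than a fixed margin (30 cm by default) beyond the
tracked boundary mark the trial as excluded.

All coordinates are continuous metres; angles are degrees, with optimal turns
stored unsigned in [0, 180].
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ArenaConfig",
    "ReturnCondition",
    "Trial",
    "TriangleGeometry",
    "InfeasibleConfigError",
    "DegenerateTriangleError",
    "generate_trial",
    "build_session",
    "triangle_of",
    "flag_out_of_border",
]

#: collinearity tolerance for triangle geometry, metres
DEGENERACY_TOL = 1e-9

#: attempts before declaring a cone-placement configuration infeasible
_MAX_ATTEMPTS = 10_000


class InfeasibleConfigError(ValueError):
    """No cone layout satisfying the constraints was found in bounded attempts."""


class DegenerateTriangleError(ValueError):
    """Cones are collinear (or coincident) within tolerance."""


class ReturnCondition(enum.Enum):
    """Environment manipulation applied during the return leg only."""

    A_no_change = "A"
    B_boundaries_removed = "B"
    C_surface_removed = "C"

    def __str__(self) -> str:  # compact single-letter form for tables
        return self.value


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry of the tracked space and session composition.

    Parameters
    ----------
    side_length:
        Side of the square tracked space, metres.
    border_margin:
        How far beyond the boundary a return path may stray before the trial
        is flagged out-of-border, metres.
    leg_length_range:
        (min, max) length of each guided leg, metres.
    turn_angle_range:
        (min, max) unsigned rotation away from straight-ahead performed at
        cone 2, degrees (0 would keep walking in a straight line).
    placement_margin:
        Minimum distance of any cone from a wall, metres.
    environments:
        Number of distinct virtual environments per session.
    trials_per_environment:
        Trials in each environment; must equal 3 x conditions_per_environment_each.
    conditions_per_environment_each:
        Presentations of each return condition per environment.
    """

    side_length: float = 3.5
    border_margin: float = 0.30
    leg_length_range: tuple[float, float] = (1.5, 3.0)
    turn_angle_range: tuple[float, float] = (50.0, 120.0)
    placement_margin: float = 0.10
    environments: int = 3
    trials_per_environment: int = 9
    conditions_per_environment_each: int = 3

    def __post_init__(self) -> None:
        if not (self.side_length > 0 and math.isfinite(self.side_length)):
            raise ValueError("side_length must be positive and finite")
        if self.border_margin < 0:
            raise ValueError("border_margin must be non-negative")
        lo, hi = self.leg_length_range
        if not (0 < lo <= hi):
            raise ValueError("leg_length_range must be positive and ordered")
        alo, ahi = self.turn_angle_range
        if not (0 <= alo <= ahi <= 180):
            raise ValueError("turn_angle_range must lie in [0, 180] and be ordered")
        if self.placement_margin < 0:
            raise ValueError("placement_margin must be non-negative")
        if self.trials_per_environment != 3 * self.conditions_per_environment_each:
            raise ValueError(
                "trials_per_environment must equal 3 x conditions_per_environment_each"
            )
        half = self.side_length / 2 - self.placement_margin
        if half <= 0:
            raise ValueError("placement_margin leaves no room for cones")
        if lo > 2 * half * math.sqrt(2):
            raise InfeasibleConfigError(
                f"minimum leg length {lo} m cannot fit inside the "
                f"{self.side_length} m arena with placement margin "
                f"{self.placement_margin} m"
            )

    @property
    def half_side(self) -> float:
        return self.side_length / 2

    @property
    def trials_per_session(self) -> int:
        return self.environments * self.trials_per_environment


@dataclass
class Trial:
    """One triangle-completion trial.

    ``response`` and ``return_path`` are absent until an agent (or a loaded
    data file) supplies them; ``excluded_out_of_border`` is set by the
    exclusion filter, which never drops rows.
    """

    participant_id: str
    environment: int
    trial_index: int
    c1: np.ndarray
    c2: np.ndarray
    c3: np.ndarray
    condition: ReturnCondition
    response: np.ndarray | None = None
    return_path: np.ndarray | None = None
    excluded_out_of_border: bool = False

    def __post_init__(self) -> None:
        self.c1 = np.asarray(self.c1, dtype=float)
        self.c2 = np.asarray(self.c2, dtype=float)
        self.c3 = np.asarray(self.c3, dtype=float)
        for c in (self.c1, self.c2, self.c3):
            if c.shape != (2,) or not np.all(np.isfinite(c)):
                raise ValueError("cone coordinates must be finite 2-vectors")


@dataclass(frozen=True)
class TriangleGeometry:
    """Side lengths and the optimal return turn of one trial triangle.

    ``optimal_turn_at_c3`` is the unsigned rotation, in degrees, from the
    incoming heading (c3 - c2) to the homing bearing (c1 - c3).
    """

    leg1: float
    leg2: float
    return_leg: float
    optimal_turn_at_c3: float


def _inside_square(p: np.ndarray, half: float) -> bool:
    return bool(np.all(np.abs(p) <= half))


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_trial(
    config: ArenaConfig,
    rng_seed: int | np.random.Generator,
    *,
    participant_id: str = "P000",
    environment: int = 1,
    trial_index: int = 1,
    condition: ReturnCondition = ReturnCondition.A_no_change,
) -> Trial:
    """Sample one cone layout by rejection.

    c1 is uniform in the arena shrunk by the placement margin; c2 and c3
    follow from a uniform leg length and (at c2) a uniform turn angle with a
    random sign, each re-drawn until all cones lie inside the shrunk arena.
    Deterministic for a fixed seed.

    Raises
    ------
    InfeasibleConfigError
        If no layout satisfying the constraints is found within bounded
        attempts; the message names the violated constraint.
    """
    rng = _as_rng(rng_seed)
    half = config.half_side - config.placement_margin
    lo, hi = config.leg_length_range
    alo, ahi = config.turn_angle_range

    last_violation = "cone inside arena"
    for _ in range(_MAX_ATTEMPTS):
        c1 = rng.uniform(-half, half, size=2)
        heading = rng.uniform(0.0, 2 * math.pi)
        leg1 = rng.uniform(lo, hi)
        c2 = c1 + leg1 * np.array([math.cos(heading), math.sin(heading)])
        if not _inside_square(c2, half):
            last_violation = f"cone 2 inside arena (leg length {lo}-{hi} m)"
            continue
        # turn at c2 is the walker's rotation away from straight-ahead
        turn = math.radians(rng.uniform(alo, ahi)) * rng.choice([-1.0, 1.0])
        leg2 = rng.uniform(lo, hi)
        heading2 = heading + turn
        c3 = c2 + leg2 * np.array([math.cos(heading2), math.sin(heading2)])
        if not _inside_square(c3, half):
            last_violation = f"cone 3 inside arena (leg length {lo}-{hi} m)"
            continue
        return Trial(
            participant_id=participant_id,
            environment=environment,
            trial_index=trial_index,
            c1=c1,
            c2=c2,
            c3=c3,
            condition=condition,
        )
    raise InfeasibleConfigError(
        f"no cone layout found in {_MAX_ATTEMPTS} attempts; "
        f"violated constraint: {last_violation}"
    )


def build_session(
    config: ArenaConfig,
    participant_id: str,
    rng_seed: int | np.random.Generator,
) -> list[Trial]:
    """Generate a full session: ``environments x trials_per_environment`` trials.

    Within every environment each return condition appears exactly
    ``conditions_per_environment_each`` times, in a seed-determined
    pseudo-random order.
    """
    rng = _as_rng(rng_seed)
    trials: list[Trial] = []
    idx = 0
    for env in range(1, config.environments + 1):
        conditions = list(ReturnCondition) * config.conditions_per_environment_each
        order = rng.permutation(len(conditions))
        for k in order:
            idx += 1
            trials.append(
                generate_trial(
                    config,
                    rng,
                    participant_id=participant_id,
                    environment=env,
                    trial_index=idx,
                    condition=conditions[k],
                )
            )
    return trials


def triangle_of(trial: Trial) -> TriangleGeometry:
    """Side lengths and optimal return turn of a trial's triangle.

    Raises :class:`DegenerateTriangleError` when the cones are collinear or
    coincident within ``DEGENERACY_TOL``.
    """
    v12 = trial.c2 - trial.c1
    v23 = trial.c3 - trial.c2
    v31 = trial.c1 - trial.c3
    leg1 = float(np.hypot(*v12))
    leg2 = float(np.hypot(*v23))
    return_leg = float(np.hypot(*v31))
    if min(leg1, leg2, return_leg) <= DEGENERACY_TOL:
        raise DegenerateTriangleError("coincident cones")
    # twice the triangle area; zero iff collinear
    cross = abs(v12[0] * v23[1] - v12[1] * v23[0])
    if cross / max(leg1, leg2) <= DEGENERACY_TOL:
        raise DegenerateTriangleError("collinear cones")
    turn = unsigned_angle_between(v23, v31)
    return TriangleGeometry(leg1, leg2, return_leg, turn)


def unsigned_angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two 2-vectors, degrees in [0, 180]."""
    dot = float(u[0] * v[0] + u[1] * v[1])
    cross = float(u[0] * v[1] - u[1] * v[0])
    return math.degrees(abs(math.atan2(cross, dot)))


def flag_out_of_border(return_path: np.ndarray, config: ArenaConfig) -> bool:
    """True iff any path point lies strictly more than ``border_margin``
    outside the arena square, measured as per-axis excess beyond the wall.

    A point exactly at the margin is *not* flagged (strict inequality).
    """
    path = np.asarray(return_path, dtype=float)
    if path.size == 0:
        raise ValueError("empty return path")
    path = np.atleast_2d(path)
    excess = np.abs(path) - config.half_side
    return bool(np.any(excess > config.border_margin))
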