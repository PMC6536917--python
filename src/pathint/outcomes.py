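"""Per-trial performance measures and per-participant aggregation.

Three measures quantify how well the unguided return leg closed the triangle:

* **absolute distance error** — Euclidean distance (m) between the response
  and the true location of cone 1; the primary outcome.
* **proportional angular error** — unsigned rotation performed at cone 3
  toward the response, divided by the optimal rotation toward cone 1.
  1.0 is a perfect rotation; the ratio is undefined when the optimal turn is
  below a small floor (default 5 degrees) that guards against blow-up.
* **proportional linear error** — Euclidean distance travelled from cone 3
  to the response, divided by the required distance from cone 3 to cone 1.
  1.0 is perfect; < 1 undershoots, > 1 overshoots.

The proportional measures are ratios (performed/optimal, travelled/required);
a secondary magnitude form |ratio - 1| is also emitted for analyses of
accuracy irrespective of direction.  Participant summaries are unweighted
means over viable (non-excluded) trials only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Trial, ReturnCondition, triangle_of, unsigned_angle_between

__all__ = [
    "ANGULAR_FLOOR_DEG",
    "OutcomeRecord",
    "ParticipantSummary",
    "absolute_distance_error",
    "proportional_angular_error",
    "proportional_linear_error",
    "performed_turn",
    "score_trial",
    "outcomes_table",
    "summarize_participant",
    "trial_accounting",
]

#: optimal turns below this (degrees) leave the angular ratio undefined
ANGULAR_FLOOR_DEG = 5.0


@dataclass(frozen=True)
class OutcomeRecord:
    """The three error measures for one trial.

    ``proportional_angular_error`` is NaN and ``valid_angular`` False when the
    optimal turn is below the floor.
    """

    absolute_distance_error: float
    proportional_angular_error: float
    proportional_linear_error: float
    valid_angular: bool


@dataclass
class ParticipantSummary:
    """Per-participant aggregates over viable trials.

    ``viable`` is False when every trial was excluded; the means are then NaN
    and the participant is dropped from downstream participant-level analyses.
    """

    participant_id: str
    n_viable: int
    mean_abs_error: float
    mean_prop_angular: float
    mean_prop_linear: float
    per_condition_means: dict = field(default_factory=dict)

    @property
    def viable(self) -> bool:
        return self.n_viable > 0


def absolute_distance_error(response: np.ndarray, goal_c1: np.ndarray) -> float:
    """Euclidean distance (m) between the response and the true cone 1."""
    response = np.asarray(response, dtype=float)
    goal_c1 = np.asarray(goal_c1, dtype=float)
    if not (np.all(np.isfinite(response)) and np.all(np.isfinite(goal_c1))):
        raise ValueError("non-finite coordinates")
    d = response - goal_c1
    return float(math.hypot(d[0], d[1]))


def proportional_angular_error(
    performed_turn_deg: float,
    optimal_turn_deg: float,
    floor: float = ANGULAR_FLOOR_DEG,
) -> float:
    """performed / optimal rotation; NaN when the optimal turn is below ``floor``."""
    if performed_turn_deg < 0 or optimal_turn_deg < 0:
        raise ValueError("turns must be unsigned (non-negative degrees)")
    if floor <= 0:
        raise ValueError("floor must be positive")
    if optimal_turn_deg < floor:
        return float("nan")
    return performed_turn_deg / optimal_turn_deg


def proportional_linear_error(travelled: float, required: float, tol: float = 1e-9) -> float:
    """travelled / required return distance; fails on degenerate triangles."""
    if travelled < 0:
        raise ValueError("travelled distance must be non-negative")
    if required <= tol:
        raise ValueError("required distance is degenerate (cone 3 at cone 1)")
    return travelled / required


def performed_turn(trial: Trial) -> float:
    """Unsigned rotation (deg) at cone 3 from the incoming heading to the response."""
    if trial.response is None:
        raise ValueError("trial has no response")
    incoming = trial.c3 - trial.c2
    outgoing = np.asarray(trial.response, dtype=float) - trial.c3
    return unsigned_angle_between(incoming, outgoing)


def score_trial(trial: Trial, floor: float = ANGULAR_FLOOR_DEG) -> OutcomeRecord:
    """Compute all three measures for a responded trial."""
    geom = triangle_of(trial)
    abs_err = absolute_distance_error(trial.response, trial.c1)
    travelled = absolute_distance_error(trial.response, trial.c3)
    ang = proportional_angular_error(performed_turn(trial), geom.optimal_turn_at_c3, floor)
    lin = proportional_linear_error(travelled, geom.return_leg)
    return OutcomeRecord(abs_err, ang, lin, valid_angular=not math.isnan(ang))


def outcomes_table(trials: list[Trial], floor: float = ANGULAR_FLOOR_DEG) -> pd.DataFrame:
    """Tidy per-trial outcome table (one row per trial, excluded rows kept).

    Excluded or unanswered trials carry NaN measures; the ``excluded`` flag is
    the only thing the exclusion filter ever sets — rows are never dropped.
    """
    rows = []
    for t in trials:
        if t.response is not None:
            rec = score_trial(t, floor)
            abs_err, ang, lin, valid = (
                rec.absolute_distance_error,
                rec.proportional_angular_error,
                rec.proportional_linear_error,
                rec.valid_angular,
            )
        else:
            abs_err = ang = lin = float("nan")
            valid = False
        rows.append(
            {
                "participant_id": t.participant_id,
                "environment": t.environment,
                "trial_index": t.trial_index,
                "condition": t.condition.value,
                "abs_error_m": abs_err,
                "prop_angular": ang,
                "prop_linear": lin,
                "abs_dev_angular": abs(ang - 1.0) if valid else float("nan"),
                "abs_dev_linear": abs(lin - 1.0) if not math.isnan(lin) else float("nan"),
                "valid_angular": valid,
                "excluded": t.excluded_out_of_border,
            }
        )
    return pd.DataFrame(rows)


def summarize_participant(outcomes: pd.DataFrame) -> ParticipantSummary:
    """Aggregate one participant's outcome rows into unweighted means.

    Only viable (non-excluded, responded) trials enter the means; the angular
    mean additionally requires ``valid_angular``.
    """
    pids = outcomes["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("summarize_participant expects rows of a single participant")
    pid = str(pids[0])
    viable = outcomes[(~outcomes["excluded"]) & outcomes["abs_error_m"].notna()]
    n_viable = len(viable)
    if n_viable == 0:
        return ParticipantSummary(pid, 0, float("nan"), float("nan"), float("nan"), {})
    per_condition = {
        cond: {
            "abs_error_m": float(sub["abs_error_m"].mean()),
            "prop_angular": float(sub.loc[sub["valid_angular"], "prop_angular"].mean()),
            "prop_linear": float(sub["prop_linear"].mean()),
        }
        for cond, sub in viable.groupby("condition")
    }
    return ParticipantSummary(
        participant_id=pid,
        n_viable=n_viable,
        mean_abs_error=float(viable["abs_error_m"].mean()),
        mean_prop_angular=float(viable.loc[viable["valid_angular"], "prop_angular"].mean()),
        mean_prop_linear=float(viable["prop_linear"].mean()),
        per_condition_means=per_condition,
    )


def trial_accounting(outcomes: pd.DataFrame) -> dict:
    """Administered / excluded / viable counts and the exclusion percentage."""
    administered = len(outcomes)
    excluded = int(outcomes["excluded"].sum())
    viable = administered - excluded
    pct = 100.0 * excluded / administered if administered else float("nan")
    return {
        "administered": administered,
        "excluded": excluded,
        "viable": viable,
        "exclusion_pct": pct,
    }
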