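"""Synthetic agent-based cohort generator.

Stands in for a clinical study population: healthy controls (HC), MCI
patients with a negative CSF Alzheimer's biomarker profile (MCI-), with a
positive profile (MCI+), and patients without CSF data (MCI-unknown).  Each
participant is a noisy path integrator characterised by four parameters:

* ``heading_noise_sd`` — zero-mean Gaussian noise (degrees) on the homing
  rotation performed at cone 3, one draw per trial;
* ``distance_gain`` — mean multiplicative gain on the required return
  distance (gain < 1 reproduces the systematic undershoot typical of
  tethered-space homing);
* ``distance_noise_cv`` — coefficient of variation of a mean-one lognormal
  multiplier on the walked distance;
* ``wander_sd`` — per-step lateral random-walk noise (m) on the executed
  return path, the mechanism by which trials stray out of the tracked
  boundary and get excluded.

Group differences are concentrated on the linear (distance) component, the
pattern reported for biomarker-positive patients; angular noise is shared
across groups by default.  Covariates follow the published group demographics
(age, sex, education, ACE-R, NART); CSF amyloid-beta and total tau are drawn
from lognormals either side of the clinical positivity thresholds; ROI
volumes are literature-plausible synthetic values with group-level atrophy
shifts and a configurable negative correlation between entorhinal (EC/pmEC)
volume and a participant's mean error.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import ArenaConfig, Trial, build_session, flag_out_of_border, triangle_of
from .outcomes import outcomes_table, summarize_participant

__all__ = [
    "Group",
    "AgentParams",
    "CsfGenerator",
    "GroupSpec",
    "ParticipantRecord",
    "ROI_NAMES",
    "classify_csf",
    "simulate_return",
    "default_group_specs",
    "generate_cohort",
]

#: step length (m) at which the executed return path is discretized
STEP_M = 0.05

#: CSF positivity thresholds (pg/ml) and ratio cut
ABETA_CUT = 550.0
TAU_CUT = 375.0
RATIO_CUT = 0.8

ROI_NAMES = ("EC", "alEC", "pmEC", "hippocampus", "PCC", "isthmus")

#: hemisphere-averaged ROI volume means and SDs, mm^3 (synthetic calibration —
#: literature-plausible scales, not values from any single study)
_ROI_MEANS = {
    "EC": 950.0,
    "alEC": 260.0,
    "pmEC": 230.0,
    "hippocampus": 3500.0,
    "PCC": 3900.0,
    "isthmus": 2700.0,
}
_ROI_SDS = {
    "EC": 110.0,
    "alEC": 40.0,
    "pmEC": 35.0,
    "hippocampus": 350.0,
    "PCC": 420.0,
    "isthmus": 320.0,
}

#: ROIs whose volume is generated with an explicit correlation to performance
_PERFORMANCE_COUPLED_ROIS = ("EC", "pmEC")


class Group(enum.Enum):
    HC = "HC"
    MCI_neg = "MCI_neg"
    MCI_pos = "MCI_pos"
    MCI_unknown = "MCI_unknown"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class AgentParams:
    """Generative noise/gain parameters of one simulated path integrator."""

    heading_noise_sd: float  # degrees
    distance_gain: float  # dimensionless, > 0
    distance_noise_cv: float  # dimensionless
    wander_sd: float  # metres per step

    def __post_init__(self) -> None:
        if self.heading_noise_sd < 0 or self.distance_noise_cv < 0 or self.wander_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.distance_gain <= 0:
            raise ValueError("distance_gain must be positive")


@dataclass(frozen=True)
class CsfGenerator:
    """Lognormal medians / log-SDs for CSF analytes, per intended label."""

    abeta_median: float
    abeta_sigma: float
    tau_median: float
    tau_sigma: float
    ptau_median: float = 60.0
    ptau_sigma: float = 0.3


@dataclass(frozen=True)
class GroupSpec:
    """Everything needed to simulate one diagnostic group."""

    label: Group
    n: int
    agent_means: AgentParams
    between_participant_sd: AgentParams
    covariate_means_sds: dict  # name -> (mean, sd) for age, education, ace_r, nart
    sex_fraction_male: float
    csf_generator: CsfGenerator | None  # None -> no CSF workup (HC / unknown)
    volume_shift: dict = field(default_factory=dict)  # ROI -> shift in SD units

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group n must be positive")
        if not 0.0 <= self.sex_fraction_male <= 1.0:
            raise ValueError("sex_fraction_male must be a proportion")


@dataclass
class ParticipantRecord:
    participant_id: str
    group: Group
    age: float
    sex: str  # "M" / "F"
    education: float
    ace_r: float
    nart: float
    csf_abeta: float  # NaN when no CSF workup
    csf_tau: float
    csf_ptau: float
    biomarker_status: str  # "positive" / "negative" / "unknown"
    roi_volumes: dict  # ROI -> mm^3
    icv: float  # mm^3
    agent: AgentParams | None = None

    @property
    def normalized_volumes(self) -> dict:
        return {k: v / self.icv for k, v in self.roi_volumes.items()}


def classify_csf(abeta: float, tau: float, rule: str = "conjunction") -> str:
    """Biomarker positivity from CSF amyloid-beta and total tau (pg/ml).

    The clinical rule is the conjunction: amyloid < 550 AND tau > 375 AND
    tau/amyloid > 0.8.  ``rule="disjunction"`` accepts any single criterion.
    """
    if not (abeta > 0 and tau > 0 and math.isfinite(abeta) and math.isfinite(tau)):
        raise ValueError("CSF values must be positive and finite")
    crit = (abeta < ABETA_CUT, tau > TAU_CUT, tau / abeta > RATIO_CUT)
    if rule == "conjunction":
        return "positive" if all(crit) else "negative"
    if rule == "disjunction":
        return "positive" if any(crit) else "negative"
    raise ValueError(f"unknown rule {rule!r}")


def _rotate(u: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([c * u[0] - s * u[1], s * u[0] + c * u[1]])


def simulate_return(
    trial: Trial, params: AgentParams, rng_seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the unguided return leg of one trial.

    The agent rotates at cone 3 by the optimal homing turn plus Gaussian
    heading noise, then walks ``required x gain x LogNormal(cv)`` metres in
    that direction.  The path is discretized at 0.05 m steps with lateral
    Gaussian wander per step; the final point is the logged response.

    Returns ``(return_path, response)``; the trial object is not modified.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    geom = triangle_of(trial)
    u_home = (trial.c1 - trial.c3) / geom.return_leg

    heading_err = math.radians(rng.normal(0.0, params.heading_noise_sd)) if params.heading_noise_sd > 0 else 0.0
    direction = _rotate(u_home, heading_err)

    dist = geom.return_leg * params.distance_gain
    if params.distance_noise_cv > 0:
        sigma = math.sqrt(math.log1p(params.distance_noise_cv**2))
        dist *= math.exp(rng.normal(-0.5 * sigma * sigma, sigma))  # mean-one lognormal

    n_full = int(dist // STEP_M)
    marks = np.arange(1, n_full + 1) * STEP_M
    if dist - n_full * STEP_M > 1e-12 or n_full == 0:
        marks = np.append(marks, dist)
    lateral = np.array([-direction[1], direction[0]])
    if params.wander_sd > 0:
        offsets = np.cumsum(rng.normal(0.0, params.wander_sd, size=marks.size))
    else:
        offsets = np.zeros(marks.size)
    path = trial.c3 + np.outer(marks, direction) + np.outer(offsets, lateral)
    return path, path[-1].copy()


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _draw_agent(rng: np.random.Generator, means: AgentParams, sds: AgentParams) -> AgentParams:
    return AgentParams(
        heading_noise_sd=max(0.0, rng.normal(means.heading_noise_sd, sds.heading_noise_sd)),
        distance_gain=max(0.1, rng.normal(means.distance_gain, sds.distance_gain)),
        distance_noise_cv=max(0.01, rng.normal(means.distance_noise_cv, sds.distance_noise_cv)),
        wander_sd=max(0.0, rng.normal(means.wander_sd, sds.wander_sd)),
    )


def _draw_csf(rng: np.random.Generator, gen: CsfGenerator, intended: str, max_tries: int = 1000):
    """Draw (abeta, tau, ptau) consistent with the intended biomarker label."""
    for _ in range(max_tries):
        abeta = gen.abeta_median * math.exp(rng.normal(0.0, gen.abeta_sigma))
        tau = gen.tau_median * math.exp(rng.normal(0.0, gen.tau_sigma))
        if classify_csf(abeta, tau) == intended:
            ptau = gen.ptau_median * math.exp(rng.normal(0.0, gen.ptau_sigma))
            return abeta, tau, ptau
    raise RuntimeError(
        f"CSF generator cannot reach intended label {intended!r} "
        f"in {max_tries} draws; generator parameters are inconsistent with the label"
    )


# ---------------------------------------------------------------------------
# study-condition defaults

_BETWEEN_SD = AgentParams(
    heading_noise_sd=4.0, distance_gain=0.08, distance_noise_cv=0.08, wander_sd=0.02
)

_POSITIVE_CSF = CsfGenerator(
    abeta_median=420.0, abeta_sigma=0.22, tau_median=560.0, tau_sigma=0.30, ptau_median=85.0
)
_NEGATIVE_CSF = CsfGenerator(
    abeta_median=820.0, abeta_sigma=0.22, tau_median=240.0, tau_sigma=0.30, ptau_median=50.0
)


def default_group_specs(null: bool = False) -> list[GroupSpec]:
    """The four study groups at their published sizes and demographics.

    Agent parameters place the impairment of the biomarker-positive group on
    the distance (linear) component — a lower gain and a larger distance
    noise CV — with angular noise shared across groups.  ``null=True`` makes
    the groups fully exchangeable — identical agent parameters, covariate
    distributions and sex fractions (CSF generators untouched) — for
    calibration of type-I error and chance-level classification.
    """
    hc_agent = AgentParams(heading_noise_sd=25.0, distance_gain=0.80,
                           distance_noise_cv=0.40, wander_sd=0.19)
    neg_agent = AgentParams(heading_noise_sd=25.0, distance_gain=0.78,
                            distance_noise_cv=0.42, wander_sd=0.20)
    pos_agent = AgentParams(heading_noise_sd=25.0, distance_gain=0.55,
                            distance_noise_cv=0.70, wander_sd=0.24)
    unk_agent = AgentParams(heading_noise_sd=25.0, distance_gain=0.68,
                            distance_noise_cv=0.52, wander_sd=0.21)
    if null:
        neg_agent = pos_agent = unk_agent = hc_agent

    def shifts(h, e, a, p, pcc, isth):
        return dict(zip(ROI_NAMES, (e, a, p, h, pcc, isth)))

    specs = [
        GroupSpec(
            label=Group.HC, n=41, agent_means=hc_agent, between_participant_sd=_BETWEEN_SD,
            covariate_means_sds={"age": (69.3, 7.5), "education": (14.8, 3.61),
                                 "ace_r": (97.2, 3.2), "nart": (6.28, 3.40)},
            sex_fraction_male=0.36, csf_generator=None,
            volume_shift=shifts(0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        ),
        GroupSpec(
            label=Group.MCI_neg, n=14, agent_means=neg_agent, between_participant_sd=_BETWEEN_SD,
            covariate_means_sds={"age": (71.1, 9.0), "education": (14.5, 4.4),
                                 "ace_r": (86.6, 7.6), "nart": (13.1, 8.9)},
            sex_fraction_male=0.71, csf_generator=_NEGATIVE_CSF,
            volume_shift=shifts(-0.5, -0.6, -0.5, -0.4, -0.3, -0.1),
        ),
        GroupSpec(
            label=Group.MCI_pos, n=12, agent_means=pos_agent, between_participant_sd=_BETWEEN_SD,
            covariate_means_sds={"age": (75.4, 7.0), "education": (14.5, 3.8),
                                 "ace_r": (80.1, 12.1), "nart": (9.1, 6.8)},
            sex_fraction_male=0.75, csf_generator=_POSITIVE_CSF,
            volume_shift=shifts(-0.9, -1.1, -0.9, -0.9, -0.5, -0.15),
        ),
        GroupSpec(
            label=Group.MCI_unknown, n=19, agent_means=unk_agent, between_participant_sd=_BETWEEN_SD,
            covariate_means_sds={"age": (71.7, 8.3), "education": (14.2, 3.37),
                                 "ace_r": (89.3, 5.4), "nart": (17.0, 10.95)},
            sex_fraction_male=0.63, csf_generator=None,
            volume_shift=shifts(-0.6, -0.7, -0.6, -0.5, -0.4, -0.1),
        ),
    ]
    if null:
        hc = specs[0]
        specs = [
            replace(
                g,
                covariate_means_sds=dict(hc.covariate_means_sds),
                sex_fraction_male=hc.sex_fraction_male,
            )
            for g in specs
        ]
    return specs


def generate_cohort(
    specs: list[GroupSpec],
    arena: ArenaConfig | None = None,
    rng_seed: int = 0,
    *,
    volume_error_corr: float = -0.5,
) -> tuple[pd.DataFrame, list[Trial], pd.DataFrame]:
    """Simulate the full cohort: participants, trial sessions and outcomes.

    Randomness is split into named substreams (geometry, agents, covariates,
    CSF, volumes) off one master seed, so the whole cohort is reproducible
    bit-identically from ``rng_seed``.

    ``volume_error_corr`` is the within-group correlation between the
    standardized EC / pmEC volume and the participant's standardized mean
    absolute error (negative: more atrophy, larger errors).

    Returns ``(participants, trials, outcomes)`` where ``participants`` is a
    DataFrame (one row each, with raw and ICV-normalized volumes and
    behavioural aggregates), ``trials`` the list of simulated
    :class:`~pathint.geometry.Trial` objects, and ``outcomes`` the tidy
    per-trial outcome table.
    """
    if arena is None:
        arena = ArenaConfig()
    if not -1.0 <= volume_error_corr <= 1.0:
        raise ValueError("volume_error_corr must be a correlation")
    seq = np.random.SeedSequence(rng_seed)
    rng_geom, rng_agent, rng_cov, rng_csf, rng_vol = (
        np.random.default_rng(s) for s in seq.spawn(5)
    )

    records: list[ParticipantRecord] = []
    all_trials: list[Trial] = []
    frames: list[pd.DataFrame] = []
    pid_counter = 0
    for spec in specs:
        for _ in range(spec.n):
            pid_counter += 1
            pid = f"P{pid_counter:03d}"
            cov = {
                name: _trunc_normal(rng_cov, m, s, lo=0.0, hi=110.0)
                for name, (m, s) in spec.covariate_means_sds.items()
            }
            cov["ace_r"] = min(cov["ace_r"], 100.0)
            sex = "M" if rng_cov.random() < spec.sex_fraction_male else "F"
            agent = _draw_agent(rng_agent, spec.agent_means, spec.between_participant_sd)

            session = build_session(arena, pid, rng_geom)
            for t in session:
                path, resp = simulate_return(t, agent, rng_agent)
                t.return_path = path
                t.response = resp
                t.excluded_out_of_border = flag_out_of_border(path, arena)
            all_trials.extend(session)
            frames.append(outcomes_table(session))

            if spec.csf_generator is not None:
                intended = "positive" if spec.label is Group.MCI_pos else "negative"
                abeta, tau, ptau = _draw_csf(rng_csf, spec.csf_generator, intended)
                status = classify_csf(abeta, tau)
            else:
                abeta = tau = ptau = float("nan")
                status = "unknown"

            icv = rng_vol.normal(1.50e6 + (6.0e4 if sex == "M" else 0.0), 1.3e5)
            icv = max(icv, 1.0e6)
            records.append(
                ParticipantRecord(
                    participant_id=pid, group=spec.label, age=cov["age"], sex=sex,
                    education=cov["education"], ace_r=cov["ace_r"], nart=cov["nart"],
                    csf_abeta=abeta, csf_tau=tau, csf_ptau=ptau, biomarker_status=status,
                    roi_volumes={}, icv=float(icv), agent=agent,
                )
            )

    outcomes = pd.concat(frames, ignore_index=True)
    summaries = {
        pid: summarize_participant(sub)
        for pid, sub in outcomes.groupby("participant_id", sort=False)
    }

    # ROI volumes last: EC / pmEC are coupled to each participant's realized
    # mean error via the configured correlation.
    errs = np.array([summaries[r.participant_id].mean_abs_error for r in records])
    finite = np.isfinite(errs)
    mu, sd = float(np.nanmean(errs[finite])), float(np.nanstd(errs[finite]))
    err_z = np.where(finite, (errs - mu) / (sd if sd > 0 else 1.0), 0.0)
    rho = volume_error_corr
    spill = math.sqrt(max(0.0, 1.0 - rho * rho))
    spec_of = {r.participant_id: spec for r, spec in zip(records, _expand_specs(specs))}
    for i, rec in enumerate(records):
        spec = spec_of[rec.participant_id]
        vols = {}
        for roi in ROI_NAMES:
            shift = spec.volume_shift.get(roi, 0.0)
            if roi in _PERFORMANCE_COUPLED_ROIS:
                z = rho * err_z[i] + spill * rng_vol.normal()
            else:
                z = rng_vol.normal()
            vols[roi] = max(1.0, _ROI_MEANS[roi] + (shift + z) * _ROI_SDS[roi])
        rec.roi_volumes = vols

    participants = _participants_frame(records, summaries)
    return participants, all_trials, outcomes


def _expand_specs(specs: list[GroupSpec]):
    for spec in specs:
        for _ in range(spec.n):
            yield spec


def _participants_frame(records: list[ParticipantRecord], summaries: dict) -> pd.DataFrame:
    rows = []
    for rec in records:
        s = summaries[rec.participant_id]
        row = {
            "participant_id": rec.participant_id,
            "group": rec.group.value,
            "age": rec.age,
            "sex": rec.sex,
            "education": rec.education,
            "ace_r": rec.ace_r,
            "nart": rec.nart,
            "csf_abeta": rec.csf_abeta,
            "csf_tau": rec.csf_tau,
            "csf_ptau": rec.csf_ptau,
            "biomarker_status": rec.biomarker_status,
            "icv": rec.icv,
            "n_viable": s.n_viable,
            "mean_abs_error": s.mean_abs_error,
            "mean_prop_angular": s.mean_prop_angular,
            "mean_prop_linear": s.mean_prop_linear,
        }
        for roi in ROI_NAMES:
            row[f"vol_{roi}"] = rec.roi_volumes[roi]
            row[f"nvol_{roi}"] = rec.roi_volumes[roi] / rec.icv
        rows.append(row)
    return pd.DataFrame(rows)
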