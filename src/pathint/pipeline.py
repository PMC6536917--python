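"""End-to-end pipeline: simulate -> score -> analyze -> volumetry -> classify -> report.

One master seed feeds named substreams (cohort, classification, bootstrap) so
stages are individually reproducible; the manifest written at the end records
seeds, configured parameters and the trial accounting (administered /
excluded / viable), and suffices to regenerate every output byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    AgentParams,
    CsfGenerator,
    Group,
    GroupSpec,
    ROI_NAMES,
    default_group_specs,
    generate_cohort,
)
from .diagnostics import ClassifierSpec, bootstrap_roc, roc_from_scores, threshold_report
from .geometry import ArenaConfig
from .inference import LmeSpec, csf_predictor_model, fit_lme, trial_level_table
from .io import trials_frame, write_table, write_yaml
from .outcomes import trial_accounting
from .volumetry import StepwiseConfig, backward_stepwise, roi_regression

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "config_to_dict", "config_from_dict"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    groups: list = field(default_factory=default_group_specs)
    lme: LmeSpec = field(default_factory=LmeSpec)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    stepwise_vif_threshold: float = 10.0
    stepwise_fdr_alpha: float = 0.01
    volume_error_corr: float = -0.5
    master_seed: int = 0
    output_dir: str = "pathint_out"

    def validate(self) -> None:
        """Cross-field checks run before any simulation starts."""
        sizes = {g.label: g.n for g in self.groups}
        if self.classifier.stratified:
            pn = [sizes.get(Group.MCI_pos), sizes.get(Group.MCI_neg)]
            if all(s is not None for s in pn) and self.classifier.k_folds > min(pn):
                raise ValueError(
                    f"k_folds={self.classifier.k_folds} exceeds the smallest "
                    f"contrasted class size ({min(pn)})"
                )
        if not -1.0 <= self.volume_error_corr <= 1.0:
            raise ValueError("volume_error_corr must be a correlation")
        StepwiseConfig(  # reuses its own validation
            candidate_predictors=("placeholder",),
            vif_threshold=self.stepwise_vif_threshold,
            fdr_alpha=self.stepwise_fdr_alpha,
        )


# --- config (de)serialization ------------------------------------------------


def config_to_dict(cfg: PipelineConfig) -> dict:
    def agent(a: AgentParams) -> dict:
        return dataclasses.asdict(a)

    groups = []
    for g in cfg.groups:
        groups.append(
            {
                "label": g.label.value,
                "n": g.n,
                "agent_means": agent(g.agent_means),
                "between_participant_sd": agent(g.between_participant_sd),
                "covariate_means_sds": {k: list(v) for k, v in g.covariate_means_sds.items()},
                "sex_fraction_male": g.sex_fraction_male,
                "csf_generator": dataclasses.asdict(g.csf_generator) if g.csf_generator else None,
                "volume_shift": dict(g.volume_shift),
            }
        )
    return {
        "arena": dataclasses.asdict(cfg.arena),
        "groups": groups,
        "lme": dataclasses.asdict(cfg.lme),
        "classifier": dataclasses.asdict(cfg.classifier),
        "stepwise_vif_threshold": cfg.stepwise_vif_threshold,
        "stepwise_fdr_alpha": cfg.stepwise_fdr_alpha,
        "volume_error_corr": cfg.volume_error_corr,
        "master_seed": cfg.master_seed,
        "output_dir": cfg.output_dir,
    }


def config_from_dict(data: dict) -> PipelineConfig:
    arena_d = dict(data.get("arena", {}))
    for key in ("leg_length_range", "turn_angle_range"):
        if key in arena_d:
            arena_d[key] = tuple(arena_d[key])
    arena = ArenaConfig(**arena_d)
    groups = []
    for g in data.get("groups", []):
        groups.append(
            GroupSpec(
                label=Group(g["label"]),
                n=int(g["n"]),
                agent_means=AgentParams(**g["agent_means"]),
                between_participant_sd=AgentParams(**g["between_participant_sd"]),
                covariate_means_sds={k: tuple(v) for k, v in g["covariate_means_sds"].items()},
                sex_fraction_male=float(g["sex_fraction_male"]),
                csf_generator=CsfGenerator(**g["csf_generator"]) if g.get("csf_generator") else None,
                volume_shift=dict(g.get("volume_shift", {})),
            )
        )
    lme_d = dict(data.get("lme", {}))
    if "covariates" in lme_d:
        lme_d["covariates"] = tuple(lme_d["covariates"])
    cls_d = dict(data.get("classifier", {}))
    if "features" in cls_d:
        cls_d["features"] = tuple(cls_d["features"])
    return PipelineConfig(
        arena=arena,
        groups=groups or default_group_specs(),
        lme=LmeSpec(**lme_d),
        classifier=ClassifierSpec(**cls_d),
        stepwise_vif_threshold=float(data.get("stepwise_vif_threshold", 10.0)),
        stepwise_fdr_alpha=float(data.get("stepwise_fdr_alpha", 0.01)),
        volume_error_corr=float(data.get("volume_error_corr", -0.5)),
        master_seed=int(data.get("master_seed", 0)),
        output_dir=str(data.get("output_dir", "pathint_out")),
    )


# --- the driver --------------------------------------------------------------


def _coef_rows(fit, label: str) -> pd.DataFrame:
    t = fit.coefficients.reset_index(names="term")
    t.insert(0, "model", label)
    return t


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``config.output_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = np.random.SeedSequence(config.master_seed)
    seed_cohort, seed_cls, seed_boot = (int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(3))
    manifest: dict = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "substream_seeds": {
            "cohort": seed_cohort,
            "classification": seed_cls,
            "bootstrap": seed_boot,
        },
        "config": config_to_dict(config),
        "stages": {},
    }

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            res = fn()
        except Exception as exc:  # noqa: BLE001 - stage name must propagate
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return res

    participants, trials, outcomes = run_stage(
        "simulate",
        lambda: generate_cohort(
            config.groups,
            config.arena,
            rng_seed=seed_cohort,
            volume_error_corr=config.volume_error_corr,
        ),
    )

    def _score():
        write_table(participants, out / "participants.csv")
        write_table(trials_frame(trials), out / "trials.csv")
        write_table(outcomes, out / "outcomes.csv")
        return trial_accounting(outcomes)

    accounting = run_stage("score", _score)
    manifest["trial_accounting"] = accounting
    expected = sum(g.n for g in config.groups) * config.arena.trials_per_session
    assert accounting["administered"] == expected, "trial conservation violated"

    def _analyze():
        rows = []
        fits = {}
        for contrast in ("mci_vs_hc", "pos_vs_neg"):
            table = trial_level_table(participants, outcomes, contrast)
            for response in ("abs_error_m", "prop_linear", "prop_angular"):
                spec = LmeSpec(
                    response=response, contrast=contrast, df_method=config.lme.df_method
                )
                fit = fit_lme(table, spec)
                fits[f"{contrast}:{response}"] = fit
                rows.append(_coef_rows(fit, f"{contrast}:{response}"))
        csf = csf_predictor_model(participants)
        rows.append(_coef_rows(csf, "csf_predictors"))
        pd.concat(rows, ignore_index=True).to_csv(out / "lme_coefficients.csv", index=False)
        return fits, csf

    fits, csf = run_stage("analyze", _analyze)
    manifest["lme"] = {
        key: {
            "dx_estimate_cm": round(100 * f.coef("dx")["estimate"], 2),
            "dx_se_cm": round(100 * f.coef("dx")["se"], 2),
            "dx_p": float(f.coef("dx")["p"]),
            "n_obs": f.n_obs,
            "notes": f.notes,
        }
        for key, f in fits.items()
        if "abs_error" in key or "prop" in key
    }
    manifest["csf_model"] = {
        "r_squared": csf.r_squared,
        "tau_t": float(csf.coef("z_tau")["t"]),
        "abeta_t": float(csf.coef("z_abeta")["t"]),
        "n": csf.n_obs,
    }

    def _vol():
        reports = {}
        for roi in ROI_NAMES:
            rep = roi_regression(participants, roi)
            reports[roi] = {
                "slope": float(rep.terms.loc[f"nvol_{roi}", "estimate"]),
                "p": float(rep.terms.loc[f"nvol_{roi}", "p"]),
                "r_squared": rep.r_squared,
                "n": rep.n_obs,
            }
        step = backward_stepwise(
            participants.assign(dx=(participants["group"] != "HC").astype(int)),
            StepwiseConfig(
                candidate_predictors=tuple(f"nvol_{r}" for r in ROI_NAMES),
                vif_threshold=config.stepwise_vif_threshold,
                fdr_alpha=config.stepwise_fdr_alpha,
            ),
        )
        report = {
            "per_roi": reports,
            "bonferroni_alpha": 0.05 / len(ROI_NAMES),
            "stepwise": {
                "r_squared": step.r_squared,
                "surviving_after_fdr": step.surviving_terms_after_fdr,
                "vifs": step.vifs,
                "notes": step.notes,
            },
        }
        with open(out / "regression_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
        step.terms.reset_index(names="term").to_csv(out / "stepwise_coefficients.csv", index=False)
        return report

    manifest["volumetry"] = run_stage("volumetry", _vol)

    def _classify():
        results = {}
        viable = participants[participants["n_viable"] > 0]
        for contrast in ("mci_vs_hc", "pos_vs_neg"):
            if contrast == "mci_vs_hc":
                sub = viable
                y = (sub["group"] != "HC").astype(int).to_numpy()
            else:
                sub = viable[viable["group"].isin(["MCI_pos", "MCI_neg"])]
                y = (sub["group"] == "MCI_pos").astype(int).to_numpy()
            feats = sub.assign(sex01=(sub["sex"] == "M").astype(int)).reset_index(drop=True)
            spec = ClassifierSpec(
                features=config.classifier.features,
                model=config.classifier.model,
                k_folds=config.classifier.k_folds,
                stratified=config.classifier.stratified,
                bootstrap_reps=config.classifier.bootstrap_reps,
                rng_seed=(seed_cls if contrast == "mci_vs_hc" else seed_cls + 1),
            )
            roc = bootstrap_roc(feats, y, spec)
            pd.DataFrame(
                {"fpr": roc.fpr, "tpr": roc.tpr, "threshold": roc.thresholds}
            ).to_csv(out / f"roc_{contrast}.csv", index=False)
            sens, spcf = threshold_report(
                feats["mean_abs_error"].to_numpy(), y, roc_error_threshold(feats, y)
            )
            results[contrast] = {
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "optimal_posterior_threshold": roc.optimal_threshold,
                "sensitivity_at_opt": roc.sensitivity_at_opt,
                "specificity_at_opt": roc.specificity_at_opt,
                "error_threshold_cm": round(100 * roc_error_threshold(feats, y), 1),
                "sensitivity_at_error_threshold": sens,
                "specificity_at_error_threshold": spcf,
                "n": int(len(y)),
            }
        with open(out / "roc_results.json", "w", encoding="utf-8") as fh:
            json.dump(results, fh, indent=2)
        return results

    manifest["classification"] = run_stage("classify", _classify)

    write_yaml(config_to_dict(config), out / "cohort_config.yaml")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def roc_error_threshold(feats: pd.DataFrame, labels: np.ndarray) -> float:
    """Youden-optimal cut on the raw mean error (metres), for reporting the
    operating point on the scale clinicians would use."""
    roc = roc_from_scores(feats["mean_abs_error"].to_numpy(), labels)
    thr = roc.optimal_threshold
    if not np.isfinite(thr):
        thr = float(feats["mean_abs_error"].max())
    return float(thr)
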