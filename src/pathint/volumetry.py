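"""Structure-function association: ROI volumetry regressions and the
hypothesis-free backward-stepwise search.

Per-ROI models regress the per-participant mean absolute distance error on
one ICV-normalized ROI volume, adjusting for age, sex, years of education and
the participant group's mean performance; Bonferroni adjustment across the
ROI family is the caller's responsibility.

The stepwise procedure runs three phases on a candidate set of ROI columns
with forced covariates (group, age, sex, education) that are never deleted:
(1) deletion-only search dropping whichever candidate most lowers the AIC,
until no deletion lowers it; (2) collinearity pruning, repeatedly dropping
the highest-VIF candidate above the threshold and refitting; (3)
Benjamini-Hochberg FDR at a stringent alpha (default 0.01) over the final
model's coefficients (intercept excluded), reporting the candidates that
survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "StepwiseConfig",
    "RegressionReport",
    "roi_regression",
    "backward_stepwise",
]


@dataclass(frozen=True)
class StepwiseConfig:
    """Tuning of the backward-stepwise search."""

    response: str = "mean_abs_error"
    candidate_predictors: tuple = ()
    forced_covariates: tuple = ("dx", "age", "sex01", "education")
    vif_threshold: float = 10.0
    fdr_alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.vif_threshold <= 1:
            raise ValueError("vif_threshold must exceed 1")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if not self.candidate_predictors:
            raise ValueError("candidate set must be non-empty")


@dataclass
class RegressionReport:
    """OLS terms, fit statistics, VIFs and the FDR-surviving set."""

    terms: pd.DataFrame  # estimate / se / t / p per term
    r_squared: float
    f_stat: float
    f_p: float
    n_obs: int
    vifs: dict = field(default_factory=dict)
    surviving_terms_after_fdr: list = field(default_factory=list)
    aic: float = float("nan")
    notes: list = field(default_factory=list)


def _prepare(data: pd.DataFrame) -> pd.DataFrame:
    d = data.copy()
    if "sex01" not in d.columns and "sex" in d.columns:
        d["sex01"] = (d["sex"] == "M").astype(int)
    return d


def _ols_report(d: pd.DataFrame, response: str, predictors: list) -> tuple:
    X = sm.add_constant(d[predictors].astype(float), has_constant="add")
    fit = sm.OLS(d[response].astype(float), X).fit()
    terms = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
    return fit, terms


def roi_regression(
    participants: pd.DataFrame,
    roi: str,
    response: str = "mean_abs_error",
    covariates: tuple = ("age", "sex01", "education", "group_mean_perf"),
) -> RegressionReport:
    """Regress per-participant mean error on one normalized ROI volume.

    The ``group_mean_perf`` covariate is the participant group's mean of the
    response, assigned to every member of the group (the group-mean
    performance adjustment; an unusual covariate, applied literally).
    """
    d = _prepare(participants)
    col = roi if roi in d.columns else f"nvol_{roi}"
    if col not in d.columns:
        raise KeyError(f"no ROI column {roi!r}")
    d = d[np.isfinite(d[response]) & np.isfinite(d[col])].copy()
    if "group_mean_perf" in covariates:
        d["group_mean_perf"] = d.groupby("group")[response].transform("mean")
    predictors = [col, *covariates]
    if len(d) < len(predictors) + 2:
        raise ValueError(f"{len(d)} observations cannot support {len(predictors)} predictors")
    for p in predictors:
        if float(d[p].std(ddof=0)) < 1e-15:
            raise ValueError(f"zero-variance predictor: {p!r}")
    fit, terms = _ols_report(d, response, predictors)
    return RegressionReport(
        terms=terms,
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        f_p=float(fit.f_pvalue),
        n_obs=int(fit.nobs),
        aic=float(fit.aic),
    )


def _aic_fit(d: pd.DataFrame, response: str, predictors: list, notes: list):
    """OLS fit and AIC, ridge-guarded when the design is not overdetermined."""
    n = len(d)
    if len(predictors) + 1 >= n:
        # deletion-only search may start with p >= n; fall back to a tiny
        # ridge penalty so an AIC-like criterion stays defined
        X = sm.add_constant(d[predictors].astype(float), has_constant="add")
        fit = sm.OLS(d[response].astype(float), X).fit_regularized(
            alpha=1e-6, L1_wt=0.0
        )
        resid = d[response].astype(float) - X @ fit.params
        rss = float(resid @ resid) + 1e-12
        aic = n * np.log(rss / n) + 2 * (len(predictors) + 1)
        if "ridge-guarded initial fit (p >= n)" not in notes:
            notes.append("ridge-guarded initial fit (p >= n)")
        return None, aic
    fit, _ = _ols_report(d, response, predictors)
    return fit, float(fit.aic)


def backward_stepwise(data: pd.DataFrame, config: StepwiseConfig) -> RegressionReport:
    """Three-phase backward search: AIC deletion, VIF pruning, BH-FDR.

    Forced covariates are always retained; ``surviving_terms_after_fdr``
    holds the candidate predictors whose coefficients survive
    Benjamini-Hochberg at ``fdr_alpha`` in the final model.
    """
    d = _prepare(data)
    response = config.response
    forced = [c for c in config.forced_covariates if c in d.columns]
    candidates = list(config.candidate_predictors)
    missing = [c for c in candidates if c not in d.columns]
    if missing:
        raise KeyError(f"candidate columns absent from data: {missing}")
    d = d[np.isfinite(d[response])]
    notes: list = []

    # phase 1: deletion-only AIC search over candidates
    _, current_aic = _aic_fit(d, response, forced + candidates, notes)
    improved = True
    while improved and candidates:
        improved = False
        trials = []
        for c in candidates:
            remaining = [x for x in candidates if x != c]
            fit, aic = _aic_fit(d, response, forced + remaining, notes)
            trials.append((aic, c, fit))
        best_aic = min(t[0] for t in trials)
        if best_aic < current_aic:
            # AIC ties broken by dropping the predictor with the larger p-value
            tied = [t for t in trials if abs(t[0] - best_aic) < 1e-9]
            if len(tied) > 1:
                full_fit, terms = _ols_report(d, response, forced + candidates)
                tied.sort(key=lambda t: -terms.loc[t[1], "p"])
            drop = tied[0][1]
            candidates.remove(drop)
            current_aic = best_aic
            improved = True

    # phase 2: VIF pruning, one drop at a time, recomputed after every drop
    def _vifs(cols: list) -> dict:
        X = sm.add_constant(d[cols].astype(float), has_constant="add").to_numpy()
        return {c: float(variance_inflation_factor(X, i + 1)) for i, c in enumerate(cols)}

    while candidates:
        vifs = _vifs(forced + candidates)
        cand_vifs = {c: vifs[c] for c in candidates}
        worst = max(cand_vifs, key=cand_vifs.get)
        if cand_vifs[worst] <= config.vif_threshold:
            break
        candidates.remove(worst)

    # phase 3: final fit + Benjamini-Hochberg over candidate p-values
    final_predictors = forced + candidates
    if len(final_predictors) + 1 >= len(d):
        raise ValueError(
            f"final design not identifiable: {len(final_predictors)} predictors "
            f"for {len(d)} observations; collinear/excess set: {candidates}"
        )
    fit, terms = _ols_report(d, response, final_predictors)
    rank = np.linalg.matrix_rank(sm.add_constant(d[final_predictors].astype(float)).to_numpy())
    if rank < len(final_predictors) + 1:
        raise ValueError(f"final design rank-deficient; collinear set: {final_predictors}")
    surviving: list = []
    if candidates:
        # the FDR family is every final-model coefficient except the
        # intercept (forced covariates included, as in controlling the whole
        # final model); only candidates are reported as survivors
        family = [t for t in terms.index if t != "const"]
        pvals = terms.loc[family, "p"].to_numpy()
        keep, *_ = multipletests(pvals, alpha=config.fdr_alpha, method="fdr_bh")
        surviving = [t for t, k in zip(family, keep) if k and t in candidates]
    vifs = _vifs(final_predictors) if final_predictors else {}
    return RegressionReport(
        terms=terms,
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        f_p=float(fit.f_pvalue),
        n_obs=int(fit.nobs),
        vifs=vifs,
        surviving_terms_after_fdr=surviving,
        aic=float(fit.aic),
        notes=notes,
    )
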