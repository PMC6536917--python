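"""Group inference: trial-level mixed-effects contrasts and covariate-adjusted
participant-level comparisons.

The trial-level model mirrors the study design: the response (one of the
three outcome measures) is regressed on a diagnosis x return-condition
interaction plus covariates (age, sex, years of education, ACE-R, NART and
VR environment), with a per-participant random intercept and random
coefficients over the environment factor.  Fits are REML via
:mod:`statsmodels`; denominator degrees of freedom for the fixed effects use
a Satterthwaite approximation computed here from the REML likelihood
(variance-of-variance moment matching), with a residual-df fallback.

Participant-level utilities cover the CSF biomarker predictor model (mean
error on z-scored tau and amyloid-beta), one-way ANCOVA with covariates, and
non-parametric fallbacks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams

__all__ = [
    "LmeSpec",
    "ModelFit",
    "trial_level_table",
    "fit_lme",
    "csf_predictor_model",
    "ancova_compare",
    "kruskal_wallis",
    "mann_whitney",
]

RESPONSES = ("abs_error_m", "prop_angular", "prop_linear")
CONTRASTS = ("mci_vs_hc", "pos_vs_neg")


@dataclass(frozen=True)
class LmeSpec:
    """Specification of one trial-level mixed-effects contrast."""

    response: str = "abs_error_m"
    contrast: str = "mci_vs_hc"
    covariates: tuple = ("age", "sex01", "education", "ace_r", "nart")
    include_interaction: bool = True
    df_method: str = "satterthwaite"  # or "residual"

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")
        if self.contrast not in CONTRASTS:
            raise ValueError(f"contrast must be one of {CONTRASTS}")
        if self.df_method not in ("satterthwaite", "residual"):
            raise ValueError("df_method must be 'satterthwaite' or 'residual'")


@dataclass
class ModelFit:
    """Coefficients and diagnostics of a fitted model.

    ``coefficients`` has one row per fixed-effect term with columns
    estimate / se / df / t / p.  ``notes`` records fallbacks (singular
    random-effects covariance, df method downgrades) rather than failing
    silently.
    """

    coefficients: pd.DataFrame
    variance_components: dict
    converged: bool
    n_obs: int
    n_groups: int
    r_squared: float | None = None
    f_tests: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def coef(self, term: str) -> pd.Series:
        return self.coefficients.loc[term]


def _center(s: pd.Series) -> pd.Series:
    return s - s.mean()


def trial_level_table(
    participants: pd.DataFrame, outcomes: pd.DataFrame, contrast: str
) -> pd.DataFrame:
    """Merge covariates into viable trial rows and code the diagnosis dummy.

    ``dx`` is 1 for the impaired side of the contrast (MCI as a whole, or
    biomarker-positive), 0 otherwise.  Only the groups entering the contrast
    are retained; excluded trials are dropped here.
    """
    cols = ["participant_id", "group", "age", "sex", "education", "ace_r", "nart"]
    merged = outcomes.merge(participants[cols], on="participant_id", validate="m:1")
    if contrast == "mci_vs_hc":
        merged["dx"] = (merged["group"] != "HC").astype(int)
    elif contrast == "pos_vs_neg":
        merged = merged[merged["group"].isin(["MCI_pos", "MCI_neg"])]
        merged["dx"] = (merged["group"] == "MCI_pos").astype(int)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    merged = merged[~merged["excluded"]].copy()
    merged["sex01"] = (merged["sex"] == "M").astype(int)
    return merged.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Satterthwaite machinery (REML moment matching)


def _vech(a: np.ndarray) -> np.ndarray:
    idx = np.tril_indices(a.shape[0])
    return a[idx]


def _unvech(v: np.ndarray, q: int) -> np.ndarray:
    a = np.zeros((q, q))
    idx = np.tril_indices(q)
    a[idx] = v
    return a + np.tril(a, -1).T


def _group_blocks(model) -> tuple[list, list, list]:
    """Per-group (X, Z, y) blocks of a fitted MixedLM design."""
    X = np.asarray(model.exog)
    Z = np.asarray(model.exog_re)
    y = np.asarray(model.endog)
    Xs, Zs, ys = [], [], []
    for lab in model.group_labels:
        ix = model.row_indices[lab]
        Xs.append(X[ix])
        Zs.append(Z[ix])
        ys.append(y[ix])
    return Xs, Zs, ys


def _reml_pieces(Xs, Zs, ys, G, s2):
    """REML log-likelihood and fixed-effect covariance at variance params
    (G, s2), both in data units.  Returns (loglike, cov_beta) or None when
    the implied covariance is not positive definite."""
    p = Xs[0].shape[1]
    M = np.zeros((p, p))
    Xty = np.zeros(p)
    logdet_v = 0.0
    per = []
    for X, Z, y in zip(Xs, Zs, ys):
        V = s2 * np.eye(len(y)) + Z @ G @ Z.T
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        logdet_v += 2.0 * np.sum(np.log(np.diag(L)))
        Vi_X = np.linalg.solve(V, X)
        Vi_y = np.linalg.solve(V, y)
        M += X.T @ Vi_X
        Xty += X.T @ Vi_y
        per.append((y, X, Vi_X, Vi_y))
    sign, logdet_m = np.linalg.slogdet(M)
    if sign <= 0:
        return None
    cov_beta = np.linalg.inv(M)
    beta = cov_beta @ Xty
    quad = 0.0
    for y, X, Vi_X, Vi_y in per:
        r_vi = Vi_y - Vi_X @ beta  # V^-1 (y - X beta)
        quad += (y - X @ beta) @ r_vi
    ll = -0.5 * (logdet_v + quad + logdet_m)
    return ll, cov_beta


def _satterthwaite_dfs(model, result, contrasts: np.ndarray) -> np.ndarray | None:
    """Satterthwaite denominator df for each row c of ``contrasts``.

    df = 2 g^2 / (grad_g' A grad_g) with g(theta) = c' Cov_beta(theta) c,
    A the asymptotic covariance of the REML variance-parameter estimates
    (inverse negative Hessian of the REML log-likelihood), all derivatives
    taken numerically.  Returns None if the Hessian is not usable.
    """
    Xs, Zs, ys = _group_blocks(model)
    q = Zs[0].shape[1]
    G_hat = np.asarray(result.cov_re)
    s2_hat = float(result.scale)
    theta0 = np.concatenate([_vech(G_hat), [s2_hat]])
    k = theta0.size

    def pieces(theta):
        G = _unvech(theta[:-1], q)
        s2 = theta[-1]
        if s2 <= 0:
            return None
        return _reml_pieces(Xs, Zs, ys, G, s2)

    base = pieces(theta0)
    if base is None:
        return None
    _, cov0 = base
    g0 = np.einsum("ij,jk,ik->i", contrasts, cov0, contrasts)

    steps = 1e-4 * (np.abs(theta0) + 1e-3 * s2_hat)
    # gradient of each g_i and loglike values for the Hessian
    grads = np.zeros((contrasts.shape[0], k))
    for j in range(k):
        tp, tm = theta0.copy(), theta0.copy()
        tp[j] += steps[j]
        tm[j] -= steps[j]
        pp, pm = pieces(tp), pieces(tm)
        if pp is None or pm is None:
            return None
        gp = np.einsum("ij,jk,ik->i", contrasts, pp[1], contrasts)
        gm = np.einsum("ij,jk,ik->i", contrasts, pm[1], contrasts)
        grads[:, j] = (gp - gm) / (2 * steps[j])

    def ll(theta):
        p = pieces(theta)
        return None if p is None else p[0]

    H = np.zeros((k, k))
    ll0 = ll(theta0)
    for i in range(k):
        for j in range(i, k):
            hi, hj = steps[i], steps[j]
            if i == j:
                tp, tm = theta0.copy(), theta0.copy()
                tp[i] += hi
                tm[i] -= hi
                a, b = ll(tp), ll(tm)
                if a is None or b is None:
                    return None
                H[i, i] = (a - 2 * ll0 + b) / hi**2
            else:
                tpp, tpm, tmp, tmm = (theta0.copy() for _ in range(4))
                tpp[[i, j]] += [hi, hj]
                tpm[i] += hi
                tpm[j] -= hj
                tmp[i] -= hi
                tmp[j] += hj
                tmm[[i, j]] -= [hi, hj]
                vals = [ll(t) for t in (tpp, tpm, tmp, tmm)]
                if any(v is None for v in vals):
                    return None
                H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4 * hi * hj)
    try:
        A = np.linalg.pinv(-H)
    except np.linalg.LinAlgError:
        return None
    denom = np.einsum("ij,jk,ik->i", grads, A, grads)
    with np.errstate(divide="ignore", invalid="ignore"):
        dfs = 2.0 * g0**2 / denom
    dfs[~np.isfinite(dfs)] = np.nan
    return dfs


# ---------------------------------------------------------------------------


def fit_lme(data: pd.DataFrame, spec: LmeSpec) -> ModelFit:
    """REML mixed-effects fit of one outcome measure on diagnosis, condition
    and covariates, with participant random intercepts and environment random
    coefficients.

    ``data`` is a trial-level table from :func:`trial_level_table` (viable
    trials only).  Raises on degenerate input (constant response, a group
    with < 2 participants).
    """
    resp = spec.response
    d = data.copy()
    if resp == "prop_angular":
        d = d[d["valid_angular"]]
    d = d[np.isfinite(d[resp])]
    for g in (0, 1):
        if d.loc[d["dx"] == g, "participant_id"].nunique() < 2:
            raise ValueError(f"contrast side dx={g} has fewer than 2 participants")
    if float(d[resp].std()) < 1e-12:
        raise ValueError("response is constant across trials; degenerate fit")

    notes: list[str] = []
    covariates = []
    for c in spec.covariates:
        # a covariate constant in this subset (e.g. single-sex contrast)
        # would make the design singular
        if float(d[c].astype(float).std(ddof=0)) < 1e-12:
            notes.append(f"covariate {c!r} constant; dropped")
            continue
        if c != "sex01":
            d[c] = _center(d[c].astype(float))
        covariates.append(c)
    d["env"] = d["environment"].astype(int)

    dx_term = "dx * C(condition)" if spec.include_interaction else "dx + C(condition)"
    fixed = " + ".join([dx_term, *covariates, "C(env)"])
    formula = f"{resp} ~ {fixed}"

    resp_var = float(d[resp].var())

    def _unhealthy(model, result) -> bool:
        eigs = np.linalg.eigvalsh(np.asarray(result.cov_re))
        if not result.converged or eigs.min() < 1e-8 * max(eigs.max(), 1e-12):
            return True
        p = model.exog.shape[1]
        diag = np.diag(np.asarray(result.cov_params())[:p, :p])
        if not np.all(np.isfinite(diag) & (diag > 0)):
            return True
        # a fixed-effect variance orders of magnitude beyond the response
        # variance marks a degenerate optimum
        return bool(diag.max() > 1e4 * resp_var)

    def _try_fit(model, **kw):
        # the gradient path can hit transient singular V during line search;
        # derivative-free optimizers avoid it
        for method in (["lbfgs", "powell"], ["powell"], ["nm"]):
            try:
                return model.fit(reml=True, method=method, **kw)
            except (np.linalg.LinAlgError, ValueError):
                continue
        return None

    model = smf.mixedlm(formula, d, groups=d["participant_id"], re_formula="~C(env)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = _try_fit(model)
        if result is None or _unhealthy(model, result):
            # singular / ill-conditioned random-effects covariance:
            # refit with diagonal structure, then intercept-only, logged
            q = np.asarray(model.exog_re).shape[1]
            free = MixedLMParams.from_components(
                fe_params=np.ones(model.exog.shape[1]), cov_re=np.eye(q)
            )
            diag_result = _try_fit(model, free=free)
            notes.append("random-effects covariance singular; refit with diagonal structure")
            if diag_result is None or _unhealthy(model, diag_result):
                model = smf.mixedlm(formula, d, groups=d["participant_id"], re_formula="~1")
                diag_result = _try_fit(model)
                notes.append("diagonal structure still degenerate; random intercept only")
            result = diag_result
        if result is None:
            raise RuntimeError("mixed-model fit failed under every fallback structure")
        healthy = not _unhealthy(model, result)
        if not healthy:
            notes.append("fit degenerate after all fallbacks; flagged non-converged")

    fe_names = list(result.fe_params.index)
    p = len(fe_names)
    beta = result.fe_params.to_numpy()
    cov_fe = np.asarray(result.cov_params())[:p, :p]
    with np.errstate(invalid="ignore", divide="ignore"):
        # a flagged-degenerate fit can carry invalid variances; the NaN
        # propagates to se/t/p rather than being masked
        se = np.sqrt(np.diag(cov_fe))
    resid_df = max(len(d) - p, 1)

    dfs = np.full(p, float(resid_df))
    if spec.df_method == "satterthwaite":
        sat = _satterthwaite_dfs(model, result, np.eye(p))
        if sat is None:
            notes.append("satterthwaite failed; residual df used")
        else:
            bad = ~np.isfinite(sat)
            sat[bad] = resid_df
            dfs = np.minimum(np.maximum(sat, 1.0), resid_df)

    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = beta / se
    pvals = 2 * st.t.sf(np.abs(tvals), dfs)
    coefficients = pd.DataFrame(
        {"estimate": beta, "se": se, "df": dfs, "t": tvals, "p": pvals}, index=fe_names
    )

    f_tests = {}
    if spec.include_interaction:
        inter = [i for i, n in enumerate(fe_names) if n.startswith("dx:")]
        if inter:
            L = np.zeros((len(inter), p))
            for r, i in enumerate(inter):
                L[r, i] = 1.0
            lb = L @ beta
            mid = np.linalg.solve(L @ cov_fe @ L.T, lb)
            fstat = float(lb @ mid) / len(inter)
            df2 = float(np.mean(dfs[inter]))
            f_tests["dx_x_condition"] = {
                "F": fstat,
                "df1": len(inter),
                "df2": df2,
                "p": float(st.f.sf(fstat, len(inter), df2)),
            }

    return ModelFit(
        coefficients=coefficients,
        variance_components={
            "cov_re": np.asarray(result.cov_re).tolist(),
            "scale": float(result.scale),
        },
        converged=bool(result.converged) and healthy,
        n_obs=int(len(d)),
        n_groups=int(d["participant_id"].nunique()),
        f_tests=f_tests,
        notes=notes,
    )


def csf_predictor_model(
    participants: pd.DataFrame, *, interaction: bool = False
) -> ModelFit:
    """Regress per-participant mean error on z-scored CSF tau and amyloid-beta,
    controlling for age, sex and years of education.

    Uses the biomarker-stratified patients only (those with CSF data).  With
    ``interaction=True`` a tau x amyloid term is added and compared against
    the main-effects model by likelihood ratio (reported in ``f_tests``).
    """
    d = participants[participants["biomarker_status"].isin(["positive", "negative"])].copy()
    d = d[np.isfinite(d["mean_abs_error"])]
    n_pred = 5 + (1 if interaction else 0)
    if len(d) < n_pred + 2:
        raise ValueError(f"only {len(d)} complete-CSF participants; need >= {n_pred + 2}")
    d["z_tau"] = (d["csf_tau"] - d["csf_tau"].mean()) / d["csf_tau"].std(ddof=0)
    d["z_abeta"] = (d["csf_abeta"] - d["csf_abeta"].mean()) / d["csf_abeta"].std(ddof=0)
    d["sex01"] = (d["sex"] == "M").astype(int)
    for c in ("age", "education"):
        d[c] = _center(d[c].astype(float))

    base = smf.ols("mean_abs_error ~ z_tau + z_abeta + age + sex01 + education", d).fit()
    fit = base
    f_tests = {}
    if interaction:
        full = smf.ols(
            "mean_abs_error ~ z_tau * z_abeta + age + sex01 + education", d
        ).fit()
        lr = 2 * (full.llf - base.llf)
        f_tests["tau_x_abeta_lr"] = {
            "stat": float(lr),
            "df": 1,
            "p": float(st.chi2.sf(lr, 1)),
        }
        fit = full
    coefficients = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "df": float(fit.df_resid),
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return ModelFit(
        coefficients=coefficients,
        variance_components={},
        converged=True,
        n_obs=int(fit.nobs),
        n_groups=int(fit.nobs),
        r_squared=float(fit.rsquared),
        f_tests=f_tests,
    )


def ancova_compare(
    data: pd.DataFrame,
    value: str,
    group: str = "group",
    covariates: tuple = ("age", "sex01", "education"),
    rank_transform: bool = False,
) -> ModelFit:
    """One-way ANCOVA of ``value`` across ``group`` adjusting for covariates.

    Reports the covariate-adjusted group F-test.  Any Bonferroni adjustment
    across a family of m comparisons is applied by the caller
    (alpha_adj = 0.05 / m).  ``rank_transform=True`` ranks the response first
    (the non-parametric variant).
    """
    d = data.copy()
    if "sex01" in covariates and "sex01" not in d.columns and "sex" in d.columns:
        d["sex01"] = (d["sex"] == "M").astype(int)
    d = d[np.isfinite(d[value])]
    if d[group].nunique() < 2:
        raise ValueError("need at least 2 groups")
    if rank_transform:
        d[value] = st.rankdata(d[value])
    for c in covariates:
        if d[c].std(ddof=0) < 1e-12:
            raise ValueError(f"covariate {c!r} has zero variance")
        # covariate collinear with the group indicator -> singular design
        resid = d[c] - d.groupby(group)[c].transform("mean")
        if resid.std(ddof=0) < 1e-10 * max(d[c].abs().max(), 1.0):
            raise ValueError(f"covariate {c!r} is collinear with {group!r}")
    rhs = " + ".join([f"C({group})", *covariates])
    fit = smf.ols(f"{value} ~ {rhs}", d).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    row = aov.loc[f"C({group})"]
    coefficients = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "df": float(fit.df_resid),
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return ModelFit(
        coefficients=coefficients,
        variance_components={},
        converged=True,
        n_obs=int(fit.nobs),
        n_groups=int(d[group].nunique()),
        r_squared=float(fit.rsquared),
        f_tests={
            "group": {
                "F": float(row["F"]),
                "df1": float(row["df"]),
                "df2": float(fit.df_resid),
                "p": float(row["PR(>F)"]),
            }
        },
    )


def kruskal_wallis(data: pd.DataFrame, value: str, group: str = "group") -> dict:
    """Kruskal-Wallis H across groups (demographics fallback)."""
    samples = [s[value].dropna().to_numpy() for _, s in data.groupby(group)]
    stat, p = st.kruskal(*samples)
    return {"H": float(stat), "p": float(p)}


def mann_whitney(x: np.ndarray, y: np.ndarray) -> dict:
    """Two-sample Mann-Whitney U (demographics fallback)."""
    stat, p = st.mannwhitneyu(x, y, alternative="two-sided")
    return {"U": float(stat), "p": float(p)}
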