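"""Mixed-effects contrasts, the CSF predictor model and ANCOVA utilities."""

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from pathint.cohort import default_group_specs, generate_cohort, Group
from pathint.inference import (
    LmeSpec,
    _reml_pieces,
    ancova_compare,
    csf_predictor_model,
    fit_lme,
    kruskal_wallis,
    mann_whitney,
    trial_level_table,
)


def _gaussian_trials(rng, n_part=26, effect=0.0, tau=0.2, sigma=0.5):
    """Clustered Gaussian data exactly matching LME assumptions."""
    rows = []
    for i in range(n_part):
        dx = 1 if i < n_part // 2 else 0
        u = rng.normal(0, tau)
        conds = rng.permutation(["ABC"[k % 3] for k in range(18)])
        for j in range(18):
            rows.append(
                {
                    "participant_id": f"P{i:02d}",
                    "dx": dx,
                    "environment": (j % 3) + 1,
                    "condition": conds[j],
                    "abs_error_m": 1.0 + effect * dx + u + rng.normal(0, sigma),
                    "valid_angular": True,
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows)


class TestFitLme:
    def test_recovers_injected_offset(self, rng):
        fit = fit_lme(
            _gaussian_trials(rng, effect=0.9), LmeSpec(contrast="pos_vs_neg", covariates=())
        )
        c = fit.coef("dx")
        assert abs(c["estimate"] - 0.9) < 2 * c["se"]
        assert fit.converged

    def test_constant_response_degenerate(self, rng):
        d = _gaussian_trials(rng)
        d["abs_error_m"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_lme(d, LmeSpec(contrast="pos_vs_neg", covariates=()))

    def test_too_few_participants(self, rng):
        d = _gaussian_trials(rng, n_part=26)
        d = d[d.participant_id.isin(["P00", "P13", "P14"])]
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_lme(d, LmeSpec(contrast="pos_vs_neg", covariates=()))

    def test_satterthwaite_df_at_most_residual(self, default_cohort):
        parts, _, out = default_cohort
        d = trial_level_table(parts, out, "pos_vs_neg")
        fit = fit_lme(d, LmeSpec(contrast="pos_vs_neg"))
        p = len(fit.coefficients)
        assert (fit.coefficients["df"] <= fit.n_obs - p + 1e-9).all()
        assert (fit.coefficients["df"] >= 1.0).all()
        # the diagnosis contrast is between-participant: its df must sit far
        # below the trial-level residual df
        assert fit.coef("dx")["df"] < (fit.n_obs - p) / 3

    def test_zero_variance_limit_matches_ols(self, rng):
        """With G = 0 the REML machinery reduces to ordinary least squares."""
        d = _gaussian_trials(rng, n_part=8)
        X = sm.add_constant(d[["dx"]].astype(float)).to_numpy()
        y = d["abs_error_m"].to_numpy()
        Z = np.ones((len(y), 1))
        # single-group call with zero random-effects covariance
        out = _reml_pieces([X], [Z], [y], np.zeros((1, 1)), 1.0)
        assert out is not None
        _, cov_beta = out
        ols = sm.OLS(y, X).fit()
        beta_gls = cov_beta @ (X.T @ y)
        np.testing.assert_allclose(beta_gls, ols.params, atol=1e-6)
        np.testing.assert_allclose(cov_beta, np.linalg.inv(X.T @ X), atol=1e-10)


class TestCsfPredictorModel:
    def _participants(self, rng, n=26, b_tau=0.3, b_abeta=-0.2, noise=0.15):
        z_tau = rng.normal(size=n)
        z_abeta = rng.normal(size=n)
        tau = 300 * np.exp(0.4 * z_tau)
        abeta = 600 * np.exp(0.3 * z_abeta)
        zt = (tau - tau.mean()) / tau.std()
        za = (abeta - abeta.mean()) / abeta.std()
        err = 1.5 + b_tau * zt + b_abeta * za + rng.normal(0, noise, n)
        return pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "biomarker_status": ["positive"] * (n // 2) + ["negative"] * (n - n // 2),
                "csf_tau": tau,
                "csf_abeta": abeta,
                "age": rng.normal(72, 8, n),
                "sex": rng.choice(["M", "F"], n),
                "education": rng.normal(14, 3, n),
                "mean_abs_error": err,
            }
        )

    def test_sign_recovery(self, rng):
        fit = csf_predictor_model(self._participants(rng))
        assert fit.coef("z_tau")["estimate"] > 0
        assert fit.coef("z_abeta")["estimate"] < 0

    def test_noise_free_r2_is_one(self, rng):
        fit = csf_predictor_model(self._participants(rng, noise=0.0))
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_permuted_csf_rarely_significant(self):
        hits = 0
        reps = 40
        rng = np.random.default_rng(7)
        base = self._participants(rng)
        for _ in range(reps):
            d = base.copy()
            perm = rng.permutation(len(d))
            d[["csf_tau", "csf_abeta"]] = d[["csf_tau", "csf_abeta"]].to_numpy()[perm]
            fit = csf_predictor_model(d)
            if fit.coef("z_tau")["p"] < 0.05 and fit.coef("z_abeta")["p"] < 0.05:
                hits += 1
        assert hits / reps <= 0.10

    def test_interaction_likelihood_ratio_reported(self, rng):
        fit = csf_predictor_model(self._participants(rng), interaction=True)
        assert "tau_x_abeta_lr" in fit.f_tests
        assert 0 <= fit.f_tests["tau_x_abeta_lr"]["p"] <= 1

    def test_too_few_participants_fails(self, rng):
        with pytest.raises(ValueError):
            csf_predictor_model(self._participants(rng, n=5))


class TestAncova:
    def _frame(self, rng, n=60, shift=0.0):
        g = np.repeat(["A", "B", "C"], n // 3)
        return pd.DataFrame(
            {
                "group": g,
                "value": rng.normal(0, 1, n) + shift * (g == "C"),
                "age": rng.normal(70, 8, n),
                "sex01": rng.integers(0, 2, n),
                "education": rng.normal(14, 3, n),
            }
        )

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 1000
        for _ in range(reps):
            fit = ancova_compare(self._frame(rng), "value")
            if fit.f_tests["group"]["p"] < 0.05:
                hits += 1
        assert 0.035 <= hits / reps <= 0.065

    def test_orthogonal_covariates_leave_group_effect_unchanged(self, rng):
        """When covariates are orthogonal to group membership the adjusted
        group coefficients equal the unadjusted ones."""
        d = self._frame(rng, shift=1.0)
        for c in ("age", "education"):
            d[c] = d[c] - d.groupby("group")[c].transform("mean")
        d["sex01"] = np.tile([0, 1], len(d) // 2)  # balanced within groups
        adj = ancova_compare(d, "value")
        plain = ancova_compare(d, "value", covariates=())
        for term in ("C(group)[T.B]", "C(group)[T.C]"):
            assert adj.coefficients.loc[term, "estimate"] == pytest.approx(
                plain.coefficients.loc[term, "estimate"], abs=1e-9
            )

    def test_collinear_covariate_named(self, rng):
        d = self._frame(rng)
        d["age"] = (d.group == "C").astype(float)  # perfectly group-determined
        with pytest.raises(ValueError, match="age"):
            ancova_compare(d, "value")

    def test_rank_transform_runs(self, rng):
        fit = ancova_compare(self._frame(rng, shift=2.0), "value", rank_transform=True)
        assert fit.f_tests["group"]["p"] < 0.01


def test_nonparametric_utilities(rng):
    d = pd.DataFrame({"group": np.repeat(["A", "B"], 30), "v": rng.normal(size=60)})
    d.loc[d.group == "B", "v"] += 2.0
    assert kruskal_wallis(d, "v")["p"] < 0.001
    assert mann_whitney(d.v[d.group == "A"], d.v[d.group == "B"])["p"] < 0.001
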