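#!/usr/bin/env python
"""Trial-level mixed-effects group contrasts and the CSF predictor model.

Fits the diagnosis x return-condition mixed model (random intercept +
environment random coefficients, Satterthwaite df) for each outcome measure
and both contrasts (all MCI vs HC; MCI+ vs MCI-), then regresses the
per-participant mean error on z-scored CSF tau and amyloid-beta in the
biomarker-stratified patients.

Expected pattern: the MCI+ vs MCI- contrast is carried by the distance
(linear) component, not the angular one; CSF tau loads positively and
amyloid-beta negatively on the distance error.
"""

import argparse
from pathlib import Path

import pandas as pd

from pathint.inference import LmeSpec, csf_predictor_model, fit_lme, trial_level_table
from pathint.io import OUTCOMES_COLUMNS, PARTICIPANTS_COLUMNS, read_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    parts = read_table(args.cohort / "participants.csv", PARTICIPANTS_COLUMNS)
    outcomes = read_table(args.cohort / "outcomes.csv", OUTCOMES_COLUMNS)

    rows = []
    for contrast in ("mci_vs_hc", "pos_vs_neg"):
        table = trial_level_table(parts, outcomes, contrast)
        for response in ("abs_error_m", "prop_linear", "prop_angular"):
            fit = fit_lme(table, LmeSpec(response=response, contrast=contrast))
            c = fit.coef("dx")
            unit = 100 if response == "abs_error_m" else 1
            rows.append(
                {
                    "contrast": contrast,
                    "response": response,
                    "dx_estimate": c["estimate"] * unit,
                    "dx_se": c["se"] * unit,
                    "df": c["df"],
                    "p": c["p"],
                    "interaction_p": fit.f_tests.get("dx_x_condition", {}).get("p"),
                    "n_obs": fit.n_obs,
                }
            )
            print(
                f"{contrast:10s} {response:12s} dx = {c['estimate']*unit:7.2f} "
                f"+/- {c['se']*unit:5.2f} {'cm' if unit==100 else '  '} "
                f"(df {c['df']:.0f}, p {c['p']:.4f})"
            )
    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out / "lme_contrasts.csv", index=False)

    csf = csf_predictor_model(parts)
    print(f"\nCSF model on {csf.n_obs} stratified patients: R^2 = {csf.r_squared:.3f}")
    for term in ("z_tau", "z_abeta"):
        c = csf.coef(term)
        print(f"  {term:8s} b = {c['estimate']:6.3f}  t = {c['t']:5.2f}  p = {c['p']:.4f}")
    csf.coefficients.reset_index(names="term").to_csv(args.out / "csf_model.csv", index=False)


if __name__ == "__main__":
    main()
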