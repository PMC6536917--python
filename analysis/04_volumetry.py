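#!/usr/bin/env python
"""Structure-function associations between ROI volumes and homing error.

Per-ROI regressions of the mean absolute distance error on each
ICV-normalized volume (age, sex, education and group-mean performance as
covariates; Bonferroni alpha = 0.05/6 across the ROI family), followed by
the hypothesis-free backward-stepwise search over all ROI columns with
AIC deletion, VIF pruning and BH-FDR at alpha 0.01.

Expected pattern: entorhinal (EC) and posteromedial entorhinal (pmEC)
volumes associate negatively with error; alEC, PCC and isthmus do not.
"""

import argparse
import json
from pathlib import Path

from pathint.cohort import ROI_NAMES
from pathint.io import PARTICIPANTS_COLUMNS, read_table
from pathint.volumetry import StepwiseConfig, backward_stepwise, roi_regression


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    parts = read_table(args.cohort / "participants.csv", PARTICIPANTS_COLUMNS)
    alpha_adj = 0.05 / len(ROI_NAMES)
    print(f"per-ROI regressions (Bonferroni-adjusted alpha {alpha_adj:.4f}):")
    per_roi = {}
    for roi in ROI_NAMES:
        rep = roi_regression(parts, roi)
        t = rep.terms.loc[f"nvol_{roi}"]
        flag = "*" if t["p"] < alpha_adj else " "
        print(f"  {roi:12s} slope {t['estimate']:10.1f}  p {t['p']:.4f} {flag}")
        per_roi[roi] = {"slope": float(t["estimate"]), "p": float(t["p"]),
                        "r_squared": rep.r_squared}

    step = backward_stepwise(
        parts.assign(dx=(parts.group != "HC").astype(int)),
        StepwiseConfig(candidate_predictors=tuple(f"nvol_{r}" for r in ROI_NAMES)),
    )
    print(f"\nbackward stepwise: R^2 = {step.r_squared:.3f}, "
          f"surviving FDR: {step.surviving_terms_after_fdr}")
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "volumetry_report.json").write_text(
        json.dumps(
            {
                "bonferroni_alpha": alpha_adj,
                "per_roi": per_roi,
                "stepwise": {
                    "r_squared": step.r_squared,
                    "surviving_after_fdr": step.surviving_terms_after_fdr,
                    "vifs": step.vifs,
                },
            },
            indent=2,
        )
    )


if __name__ == "__main__":
    main()
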