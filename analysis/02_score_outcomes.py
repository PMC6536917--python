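#!/usr/bin/env python
"""Re-score the simulated trials from the persisted trials.csv.

Recomputes the three error measures (absolute distance, proportional angular,
proportional linear) from cone and response coordinates alone and checks they
match the outcomes written at simulation time — the measures depend only on
the logged geometry, not on simulator internals.
"""

import argparse
from pathlib import Path

import numpy as np

from pathint.io import OUTCOMES_COLUMNS, read_table, read_trials_csv, write_table
from pathint.outcomes import outcomes_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    trials = read_trials_csv(args.cohort / "trials.csv")
    rescored = outcomes_table(trials)
    write_table(rescored, args.cohort / "outcomes_rescored.csv")

    stored = read_table(args.cohort / "outcomes.csv", OUTCOMES_COLUMNS)
    diff = np.nanmax(
        np.abs(rescored["abs_error_m"].to_numpy() - stored["abs_error_m"].to_numpy())
    )
    print(f"re-scored {len(rescored)} trials; max |abs error - stored| = {diff:.2e} m")
    viable = rescored[~rescored.excluded]
    print("\nper-measure means over viable trials:")
    print(viable[["abs_error_m", "prop_angular", "prop_linear"]].mean().round(3).to_string())


if __name__ == "__main__":
    main()
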