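"""Cost the four screening scenarios on the synthetic cohort.

Applies the eligibility rule (ever smokers aged 55-74), the 1.51 % 6-year
risk referral threshold and the printed unit costs to the fitted scenario
risks; adds threshold and deprivation-quintile sensitivity analyses and the
incidental-findings proportions among follow-up-tested participants.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lcrisk import screening_economics as econ
from lcrisk.pipeline import SCENARIO_LABELS, analyse_cohort
from lcrisk.rp_survival import predict_risk
from lcrisk.synthetic_cohort import read_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    table = read_cohort(RESULTS / "cohort.csv")
    res = analyse_cohort(table)
    params = econ.EconParams()

    print(res.economics.to_string(index=False))
    res.economics.to_csv(RESULTS / "economics.csv", index=False)

    # sensitivity: referral threshold sweep for the conventional scenario
    data = None
    from lcrisk.model_selection import build_scenario_specs
    from lcrisk.rp_survival import complete_cases

    data = complete_cases(table, build_scenario_specs()[4]).reset_index(drop=True)
    elig = econ.eligible(data, params)
    r1 = predict_risk(res.fits[1], elig, params.horizon)
    sweep = econ.threshold_sensitivity(
        r1, r1, elig["time"].to_numpy(), elig["event"].to_numpy(), params,
        [0.01, 0.0151, 0.02, 0.025, 0.03],
    )
    sweep.to_csv(RESULTS / "econ_threshold_sensitivity.csv", index=False)
    print("\nreferral-threshold sensitivity (conventional model):")
    print(sweep.to_string(index=False))

    # sensitivity: deprivation quintiles (higher Townsend = more deprived)
    quintile = pd.qcut(elig["townsend"], 5, labels=[1, 2, 3, 4, 5])
    by_depr = econ.subgroup_costs(
        r1, r1, elig["time"].to_numpy(), elig["event"].to_numpy(), params,
        quintile.astype(str).to_numpy(),
    ).sort_values("group")
    by_depr.to_csv(RESULTS / "econ_deprivation_quintiles.csv", index=False)
    print("\ncost per case detected by deprivation quintile (1 = least deprived):")
    print(by_depr.to_string(index=False))

    if res.incidental:
        print(
            f"\nincidental findings among follow-up-tested participants: "
            f"AST/ALT>2 in {res.incidental['ast_alt_ratio_gt2_pct']:.1f} %, "
            f"FEV1/FVC<0.7 in {res.incidental['fev1_fvc_lt07_pct']:.1f} % "
            f"of those without prior lung disease"
        )
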