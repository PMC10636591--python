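"""Health-economic model of risk-targeted LDCT lung-cancer screening.

Four screening scenarios share one pathway: every eligible ever-smoker aged
55-74 is contacted by telephone; those whose conventional-model 6-year risk
reaches the referral threshold (default 1.51 %) receive the scenario's
follow-up tests (none / spirometry visit / blood draw / both) to recalculate
risk; those still above threshold under the scenario's model get an LDCT
scan. A single first screen is assumed to detect a fixed fraction (default
20 %) of the lung-cancer diagnoses occurring within the horizon among the
referred. The outcome is cost per lung-cancer case detected:

    (contact + follow-up + LDCT costs) / (detect_fraction * cases among referred)

with the *unrounded* expected detections in the denominator; the rounded
count is reported separately. Unit costs are consumed as printed 2022 GBP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class EconError(ValueError):
    """Structured failure of the economic model (e.g. zero detected cases)."""


@dataclass(frozen=True)
class EconParams:
    cost_phone: float = 20.57  # GBP per telephone contact
    cost_ldct: float = 92.77  # GBP per LDCT scan (one body region)
    cost_spiro_visit: float = 63.42  # GBP per spirometry appointment
    cost_blood: float = 7.16  # GBP per blood-test appointment
    cost_both: float = 70.58  # GBP spirometry + blood
    detect_fraction: float = 0.20  # of cases found at first screen
    risk_threshold: float = 0.0151  # 6-year risk triggering referral
    horizon: float = 6.0  # years
    age_range: tuple[int, int] = (55, 74)

    def __post_init__(self) -> None:
        for c in (self.cost_phone, self.cost_ldct, self.cost_spiro_visit,
                  self.cost_blood, self.cost_both):
            if c < 0:
                raise EconError("unit costs must be >= 0")
        if not 0 < self.detect_fraction <= 1:
            raise EconError("detect_fraction must be in (0,1]")
        if not 0 < self.risk_threshold < 1:
            raise EconError("risk_threshold must be in (0,1)")

    #: follow-up cost per patient for each of the four scenarios
    def followup_cost(self, scenario: int) -> float:
        return {1: 0.0, 2: self.cost_spiro_visit, 3: self.cost_blood, 4: self.cost_both}[scenario]


@dataclass(frozen=True)
class ScenarioInputs:
    n_contacted: int
    n_followup: int  # above threshold under the conventional model
    n_referred: int  # above threshold under this scenario's model too
    n_cases: int  # referred participants diagnosed within the horizon
    followup_cost_per_patient: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.n_referred <= self.n_followup <= self.n_contacted):
            raise EconError("need n_referred <= n_followup <= n_contacted")
        if self.n_cases > self.n_referred:
            raise EconError("cases cannot exceed referrals")


@dataclass(frozen=True)
class EconResult:
    label: str
    n_contacted: int
    n_followup: int
    n_referred: int
    n_cases: int
    cost_contact_total: float
    cost_followup_total: float
    cost_ldct_total: float
    cases_detected_unrounded: float
    cases_detected_reported: int
    pct_of_screens_with_cancer: float
    pct_of_screens_detected: float
    cost_per_case_detected: int  # rounded to the nearest GBP

    @property
    def total_cost(self) -> float:
        return self.cost_contact_total + self.cost_followup_total + self.cost_ldct_total


def run_scenario(inputs: ScenarioInputs, params: EconParams) -> EconResult:
    """Cost the screening pathway for one scenario.

    Component totals are count x unit cost at full precision; only the
    reported figures are rounded. Zero expected detections is an explicit
    error, never an infinite cost.
    """
    cost_contact = inputs.n_contacted * params.cost_phone
    cost_followup = inputs.n_followup * inputs.followup_cost_per_patient
    cost_ldct = inputs.n_referred * params.cost_ldct
    detected = params.detect_fraction * inputs.n_cases
    if detected <= 0:
        raise EconError(f"no cases detected in scenario {inputs.label!r}: cost per case undefined")
    total = cost_contact + cost_followup + cost_ldct
    return EconResult(
        label=inputs.label,
        n_contacted=inputs.n_contacted,
        n_followup=inputs.n_followup,
        n_referred=inputs.n_referred,
        n_cases=inputs.n_cases,
        cost_contact_total=cost_contact,
        cost_followup_total=cost_followup,
        cost_ldct_total=cost_ldct,
        cases_detected_unrounded=detected,
        cases_detected_reported=int(round(detected)),
        pct_of_screens_with_cancer=100.0 * inputs.n_cases / inputs.n_referred
        if inputs.n_referred
        else float("nan"),
        pct_of_screens_detected=100.0 * detected / inputs.n_referred
        if inputs.n_referred
        else float("nan"),
        cost_per_case_detected=int(round(total / detected)),
    )


def eligible(table: pd.DataFrame, params: EconParams = EconParams()) -> pd.DataFrame:
    """Screening-eligible subset: ever smokers aged 55-74 (inclusive bounds,
    age in whole years at contact)."""
    lo, hi = params.age_range
    age = np.floor(table["age_entry"].to_numpy(dtype=float))
    ever = table["smoking_status"].isin(["former", "current"]).to_numpy()
    return table.loc[ever & (age >= lo) & (age <= hi)]


def scenario_inputs_from_risks(
    risks_base,
    risks_scenario,
    time,
    event,
    params: EconParams,
    followup_cost_per_patient: float = 0.0,
    label: str = "",
    threshold: float | None = None,
) -> ScenarioInputs:
    """Build scenario counts from predicted 6-year risks on the eligible set.

    The conventional model gates follow-up testing; referral requires both
    the conventional and the scenario model to reach the threshold. Cases are
    referred participants with an event inside the horizon. ``threshold``
    overrides ``params.risk_threshold`` (boundary values 0 and 1 allowed
    here, for sensitivity sweeps).
    """
    risks_base = np.asarray(risks_base, dtype=float)
    risks_scenario = np.asarray(risks_scenario, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (risks_base.shape == risks_scenario.shape == time.shape == event.shape):
        raise EconError("risk/outcome arrays must have equal length")
    thr = params.risk_threshold if threshold is None else threshold
    if not 0 <= thr <= 1:
        raise EconError("threshold outside [0,1]")
    follow = risks_base >= thr
    refer = follow & (risks_scenario >= thr)
    cases = refer & (event == 1) & (time <= params.horizon)
    return ScenarioInputs(
        n_contacted=risks_base.size,
        n_followup=int(follow.sum()),
        n_referred=int(refer.sum()),
        n_cases=int(cases.sum()),
        followup_cost_per_patient=followup_cost_per_patient,
        label=label,
    )


def threshold_sensitivity(
    risks_base, risks_scenario, time, event, params: EconParams, thresholds,
    followup_cost_per_patient: float = 0.0, label: str = "",
) -> pd.DataFrame:
    """One EconResult row per referral threshold; scenarios with zero
    detected cases are reported with missing cost columns rather than errors."""
    thresholds = list(thresholds)
    if not thresholds:
        raise EconError("empty threshold list")
    rows = []
    for thr in thresholds:
        inputs = scenario_inputs_from_risks(
            risks_base, risks_scenario, time, event, params,
            followup_cost_per_patient=followup_cost_per_patient, label=label,
            threshold=thr,
        )
        row = {"threshold": thr, "n_referred": inputs.n_referred, "n_cases": inputs.n_cases}
        try:
            res = run_scenario(inputs, params)
            row["cost_per_case_detected"] = res.cost_per_case_detected
            row["total_cost"] = res.total_cost
        except EconError:
            row["cost_per_case_detected"] = np.nan
            row["total_cost"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def subgroup_costs(
    risks_base, risks_scenario, time, event, params: EconParams, groups,
    followup_cost_per_patient: float = 0.0,
) -> pd.DataFrame:
    """Run the scenario within each subgroup (e.g. deprivation quintile).

    Contact costs are allocated per group (every group member is contacted).
    Groups with zero detected cases are flagged and skipped.
    """
    groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        m = groups == g
        if not m.any():
            continue
        inputs = scenario_inputs_from_risks(
            np.asarray(risks_base)[m], np.asarray(risks_scenario)[m],
            np.asarray(time)[m], np.asarray(event)[m], params,
            followup_cost_per_patient=followup_cost_per_patient, label=str(g),
        )
        try:
            res = run_scenario(inputs, params)
            rows.append(
                {"group": g, "n": int(m.sum()), "n_referred": res.n_referred,
                 "n_cases": res.n_cases, "cost_per_case_detected": res.cost_per_case_detected,
                 "skipped": False}
            )
        except EconError:
            rows.append(
                {"group": g, "n": int(m.sum()), "n_referred": inputs.n_referred,
                 "n_cases": inputs.n_cases, "cost_per_case_detected": np.nan, "skipped": True}
            )
    return pd.DataFrame(rows)


def incidental_findings(table: pd.DataFrame) -> dict[str, float]:
    """Proportions flagged by the follow-up tests themselves.

    AST/ALT ratio > 2 suggests (alcohol-related) liver damage; FEV1/FVC < 0.7
    among participants without a baseline lung-disease diagnosis (asthma,
    emphysema, tuberculosis or pneumonia history) suggests airway
    obstruction. Rows with zero denominators are excluded and counted.
    """
    ast = table["ast"].to_numpy(dtype=float)
    alt = table["alt"].to_numpy(dtype=float)
    ok_liver = np.isfinite(ast) & np.isfinite(alt) & (alt != 0)
    liver_flag = (ast[ok_liver] / alt[ok_liver]) > 2.0

    fev1 = table["fev1"].to_numpy(dtype=float)
    fvc = table["fvc"].to_numpy(dtype=float)
    lung_dx = (
        table[["asthma", "emphysema", "tuberculosis", "pneumonia"]]
        .fillna(0)
        .to_numpy(dtype=float)
        .sum(axis=1)
        > 0
    )
    ok_spiro = np.isfinite(fev1) & np.isfinite(fvc) & (fvc != 0) & ~lung_dx
    obstr_flag = (fev1[ok_spiro] / fvc[ok_spiro]) < 0.7

    return {
        "ast_alt_ratio_gt2_pct": 100.0 * liver_flag.mean() if ok_liver.any() else float("nan"),
        "n_liver_evaluable": int(ok_liver.sum()),
        "n_liver_excluded": int((~ok_liver).sum()),
        "fev1_fvc_lt07_pct": 100.0 * obstr_flag.mean() if ok_spiro.any() else float("nan"),
        "n_spiro_evaluable": int(ok_spiro.sum()),
        "n_spiro_excluded": int(len(table) - ok_spiro.sum()),
    }


def load_published_inputs(path=None) -> tuple[EconParams, list[ScenarioInputs]]:
    """Load screening-scenario inputs from JSON; by default the packaged
    published counts and unit costs, so the cost table can be replayed
    without any cohort."""
    import json
    from importlib import resources

    if path is None:
        text = (
            resources.files("lcrisk").joinpath("data/published_screening_inputs.json").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    payload = json.loads(text)
    p = payload["params"]
    params = EconParams(
        cost_phone=p["cost_phone"],
        cost_ldct=p["cost_ldct"],
        cost_spiro_visit=p["cost_spiro_visit"],
        cost_blood=p["cost_blood"],
        cost_both=p["cost_both"],
        detect_fraction=p["detect_fraction"],
        risk_threshold=p["risk_threshold"],
        horizon=p["horizon"],
    )
    scenarios = [
        ScenarioInputs(
            n_contacted=s["n_contacted"],
            n_followup=s["n_followup"],
            n_referred=s["n_referred"],
            n_cases=s["n_cases"],
            followup_cost_per_patient=s["followup_cost_per_patient"],
            label=s["label"],
        )
        for s in payload["scenarios"]
    ]
    return params, scenarios


def replay_published(path=None, detect_fraction: float | None = None) -> pd.DataFrame:
    """Replay the published screening cost table from its printed inputs."""
    params, scenarios = load_published_inputs(path)
    if detect_fraction is not None:
        params = EconParams(
            cost_phone=params.cost_phone, cost_ldct=params.cost_ldct,
            cost_spiro_visit=params.cost_spiro_visit, cost_blood=params.cost_blood,
            cost_both=params.cost_both, detect_fraction=detect_fraction,
            risk_threshold=params.risk_threshold, horizon=params.horizon,
        )
    return results_table([run_scenario(s, params) for s in scenarios])


def results_table(results: list[EconResult]) -> pd.DataFrame:
    """One row per scenario, mirroring the published cost table's columns."""
    return pd.DataFrame(
        [
            {
                "scenario": r.label,
                "total_cost_contact": round(r.cost_contact_total),
                "total_cost_followup": round(r.cost_followup_total),
                "n_referred": r.n_referred,
                "total_cost_ldct": round(r.cost_ldct_total),
                "n_cases_6y": r.n_cases,
                "pct_screens_with_cancer": round(r.pct_of_screens_with_cancer, 1),
                "cases_detected": r.cases_detected_reported,
                "pct_screens_detected": round(r.pct_of_screens_detected, 2),
                "cost_per_case_detected": r.cost_per_case_detected,
            }
            for r in results
        ]
    )
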