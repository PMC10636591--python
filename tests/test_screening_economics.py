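"""Screening cost model: published-table replay and structural properties."""

import numpy as np
import pandas as pd
import pytest

from lcrisk.screening_economics import (
    EconError,
    EconParams,
    ScenarioInputs,
    eligible,
    incidental_findings,
    load_published_inputs,
    replay_published,
    run_scenario,
    scenario_inputs_from_risks,
    subgroup_costs,
    threshold_sensitivity,
)


def test_published_cost_table_replays_to_the_pound():
    df = replay_published()
    assert df["cost_per_case_detected"].tolist() == [25926, 34993, 26944, 35701]
    assert df["cases_detected"].tolist() == [164, 153, 151, 151]
    assert df["pct_screens_with_cancer"].tolist() == [3.7, 4.0, 4.1, 4.3]


def test_unrounded_detection_denominator():
    """Scenario 3: 4,079,330 total cost over 151.4 expected detections gives
    26,944; rounding the denominator to 151 would wrongly give 27,015."""
    params, scenarios = load_published_inputs()
    res = run_scenario(scenarios[2], params)
    assert res.cases_detected_unrounded == pytest.approx(151.4)
    assert res.total_cost == pytest.approx(4_079_330.33, abs=0.01)
    assert res.cost_per_case_detected == 26944
    assert round(res.total_cost / 151) == 27015  # the wrong convention


def test_cost_decomposition_is_exact():
    params, scenarios = load_published_inputs()
    for s in scenarios:
        r = run_scenario(s, params)
        assert r.cost_contact_total == s.n_contacted * params.cost_phone
        assert r.cost_followup_total == s.n_followup * s.followup_cost_per_patient
        assert r.cost_ldct_total == s.n_referred * params.cost_ldct
        assert r.total_cost == r.cost_contact_total + r.cost_followup_total + r.cost_ldct_total


def test_detect_fraction_scales_cost_inversely():
    params, scenarios = load_published_inputs()
    base = run_scenario(scenarios[0], params)
    doubled = replay_published(detect_fraction=0.4)
    for got, ref in zip(doubled["cost_per_case_detected"], [25926, 34993, 26944, 35701]):
        # halving is exact on the unrounded quotient
        assert got == pytest.approx(ref / 2, abs=1.0)
    assert base.cases_detected_unrounded == pytest.approx(0.2 * 819)


def test_trivial_unit_cost_case():
    p = EconParams(cost_phone=0.0, cost_ldct=1.0, cost_spiro_visit=0.0,
                   cost_blood=0.0, cost_both=0.0, detect_fraction=1.0)
    s = ScenarioInputs(n_contacted=10, n_followup=10, n_referred=10, n_cases=10)
    assert run_scenario(s, p).cost_per_case_detected == 1


def test_zero_cases_is_structured_error():
    params, _ = load_published_inputs()
    s = ScenarioInputs(n_contacted=100, n_followup=10, n_referred=5, n_cases=0)
    with pytest.raises(EconError, match="undefined"):
        run_scenario(s, params)


def test_scenario_inputs_invariants():
    with pytest.raises(EconError):
        ScenarioInputs(n_contacted=10, n_followup=20, n_referred=5, n_cases=1)
    with pytest.raises(EconError):
        ScenarioInputs(n_contacted=100, n_followup=20, n_referred=5, n_cases=7)


def test_eligibility_rules():
    tab = pd.DataFrame(
        {
            "age_entry": [60.0, 55.0, 54.9, 74.0, 75.0, 60.0],
            "smoking_status": ["never", "former", "current", "current", "former", "current"],
        }
    )
    got = eligible(tab)
    # never-smokers excluded; age floored to whole years, inclusive [55, 74]
    assert got.index.tolist() == [1, 3, 5]


def test_scenario_inputs_from_risks_against_filter_oracle():
    rng = np.random.default_rng(8)
    n = 5000
    rb = rng.uniform(0, 0.06, n)
    rs = np.clip(rb + rng.normal(0, 0.01, n), 0, 0.2)
    time = rng.uniform(0.1, 9.0, n)
    event = rng.integers(0, 2, n)
    p = EconParams()
    got = scenario_inputs_from_risks(rb, rs, time, event, p)
    # independent brute-force filter
    follow = sum(1 for r in rb if r >= 0.0151)
    refer = sum(1 for a, b in zip(rb, rs) if a >= 0.0151 and b >= 0.0151)
    cases = sum(
        1 for a, b, t, e in zip(rb, rs, time, event)
        if a >= 0.0151 and b >= 0.0151 and e == 1 and t <= 6.0
    )
    assert (got.n_followup, got.n_referred, got.n_cases) == (follow, refer, cases)
    # identical risks: everyone followed up is referred
    same = scenario_inputs_from_risks(rb, rb, time, event, p)
    assert same.n_referred == same.n_followup
    with pytest.raises(EconError):
        scenario_inputs_from_risks(rb, rs[:-1], time, event, p)


def test_all_below_threshold_leads_to_error_path():
    p = EconParams()
    risks = np.full(100, 0.001)
    time = np.full(100, 5.0)
    event = np.zeros(100, dtype=int)
    inp = scenario_inputs_from_risks(risks, risks, time, event, p)
    assert inp.n_referred == 0
    with pytest.raises(EconError):
        run_scenario(inp, p)


def test_threshold_sensitivity_monotone():
    rng = np.random.default_rng(9)
    n = 4000
    rb = rng.uniform(0, 0.08, n)
    time = rng.uniform(0.1, 9.0, n)
    event = rng.integers(0, 2, n)
    p = EconParams()
    out = threshold_sensitivity(rb, rb, time, event, p, [0.0, 0.0151, 0.025, 1.0])
    refs = out["n_referred"].tolist()
    assert refs == sorted(refs, reverse=True)
    assert refs[0] == n  # threshold 0: everyone referred
    assert refs[-1] == 0  # threshold 1: nobody
    with pytest.raises(EconError):
        threshold_sensitivity(rb, rb, time, event, p, [])


def test_subgroup_costs():
    p = EconParams()
    rng = np.random.default_rng(10)
    n = 2000
    rb = rng.uniform(0.01, 0.05, n)
    time = np.full(n, 3.0)
    event = rng.integers(0, 2, n)
    # two identical groups -> identical cost per case
    groups = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    rb2 = np.concatenate([rb[: n // 2], rb[: n // 2]])
    ev2 = np.concatenate([event[: n // 2], event[: n // 2]])
    out = subgroup_costs(rb2, rb2, time, ev2, p, groups)
    assert out["cost_per_case_detected"].nunique() == 1
    # doubled event rate with the same referrals roughly halves the cost
    base_inp = ScenarioInputs(n_contacted=1000, n_followup=200, n_referred=200, n_cases=40)
    rich_inp = ScenarioInputs(n_contacted=1000, n_followup=200, n_referred=200, n_cases=80)
    r1, r2 = run_scenario(base_inp, p), run_scenario(rich_inp, p)
    assert r2.cost_per_case_detected == pytest.approx(r1.cost_per_case_detected / 2, rel=1e-6)
    # a group with no detectable cases is flagged and skipped
    groups = np.array(["ok"] * n, dtype=object)
    groups[:5] = "empty"
    ev3 = event.copy()
    ev3[:5] = 0
    rb3 = rb.copy()
    rb3[:5] = 0.02
    out = subgroup_costs(rb3, rb3, time, ev3, p, groups)
    assert bool(out.loc[out["group"] == "empty", "skipped"].item()) is True


def test_incidental_findings_counting():
    tab = pd.DataFrame(
        {
            "ast": [60.0] * 9 + [20.0] * 191,
            "alt": [25.0] * 200,
            "fev1": [2.0] * 200,
            "fvc": [3.2] * 100 + [2.0] * 100,
            "asthma": [0] * 200,
            "emphysema": [0] * 200,
            "tuberculosis": [0] * 200,
            "pneumonia": [0] * 200,
        }
    )
    out = incidental_findings(tab)
    assert out["ast_alt_ratio_gt2_pct"] == pytest.approx(4.5)  # 9 of 200
    assert out["fev1_fvc_lt07_pct"] == pytest.approx(50.0)  # ratio 0.625 flagged
    # zero denominators are excluded and counted
    tab.loc[0, "alt"] = 0.0
    out = incidental_findings(tab)
    assert out["n_liver_excluded"] == 1


def test_params_validation():
    with pytest.raises(EconError):
        EconParams(cost_phone=-1.0)
    with pytest.raises(EconError):
        EconParams(detect_fraction=0.0)
    with pytest.raises(EconError):
        EconParams(risk_threshold=1.0)
    # the combined follow-up cost equals spirometry + blood for the defaults
    p = EconParams()
    assert p.cost_both == pytest.approx(p.cost_spiro_visit + p.cost_blood)
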