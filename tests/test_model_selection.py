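"""Functional-form and interaction selection by AIC/BIC."""

import numpy as np
import pandas as pd
import pytest

from lcrisk.model_selection import (
    BLOOD_VARS,
    CONVENTIONAL_TERMS,
    PUBLISHED_TERMS,
    SPIRO_VARS,
    SelectionConfig,
    build_scenario_specs,
    criterion_value,
    fitting_sample,
    select_interactions,
    select_transform,
    selection_sample,
    split_indices,
)
from lcrisk.rp_survival import RPModelSpec, Term, fit
from lcrisk.synthetic_cohort import CensoringParams, GeneratorConfig, generate


def _cohort_with_truth(terms, coeffs, n=12_000, seed=0, const=-3.4):
    spec = RPModelSpec(baseline_df=1, terms=terms)
    coeffs = {"const": const, "lnt_0": 1.0, **coeffs}
    cfg = GeneratorConfig(
        n_participants=n, seed=seed, true_model=spec, true_coeffs=coeffs,
        censoring=CensoringParams(min_followup=5.1, recruitment_span=4.0, death_rate=0.0),
    )
    return generate(cfg)


BASE = RPModelSpec(baseline_df=1, terms=(Term("sex", transform="categorical"),))


def test_log_effect_selected_when_true_effect_is_log():
    """An effect linear in log(GGT) (a strongly skewed variable) should be
    recognised against linear and spline alternatives."""
    tab = _cohort_with_truth(
        (Term("sex", transform="categorical"), Term("ggt", transform="log")),
        {"sex[male]": 0.3, "ggt": 1.0},
        seed=21,
    )
    chosen = select_transform(tab, BASE, "ggt", SelectionConfig())
    assert chosen.transform == "log" and chosen.spline_df == 0


def test_spline_selected_for_u_shaped_effect():
    """A U-shaped effect of bilirubin cannot be captured by linear or log."""
    tab = _cohort_with_truth(
        (Term("sex", transform="categorical"),
         Term("bilirubin", spline_df=2, knots=(5.0, 8.0, 13.0))),
        # strong negative slope turning positive: U shape on the raw scale
        {"sex[male]": 0.3, "bilirubin": -0.35, "bilirubin_s1": 1.4},
        seed=22,
    )
    chosen = select_transform(tab, BASE, "bilirubin", SelectionConfig())
    assert chosen.spline_df >= 2


def test_tie_breaks_toward_fewer_parameters():
    cfg = SelectionConfig(criterion="AIC")
    f_small = fit(
        _cohort_with_truth((), {}, n=2000, seed=3), RPModelSpec(baseline_df=1, terms=())
    )
    # identical loglik, differing df: the smaller model must win the key order
    assert criterion_value(f_small, cfg) < criterion_value(
        type(f_small)(**{**f_small.__dict__, "df_model": f_small.df_model + 1}), cfg
    )


def test_true_interaction_is_selected():
    """A real sex x biomarker interaction should be kept by forward AIC."""
    truth = Term("ggt", transform="log", by=("sex",), center=3.27)
    tab = _cohort_with_truth(
        (Term("sex", transform="categorical"), truth),
        {"sex[male]": 0.3, "ggt": 0.4, "ggt:sex[male]": 0.8},
        seed=23,
    )
    spec = RPModelSpec(
        baseline_df=1,
        terms=(Term("sex", transform="categorical"), Term("ggt", transform="log", center=3.27)),
    )
    chosen = select_interactions(tab, spec, "ggt", SelectionConfig())
    assert "sex" in chosen.by


def test_null_interaction_selection_rates():
    """Under the null, AIC keeps a partner roughly at rate P(chi2_df > 2 df)
    and BIC keeps strictly fewer over the same seeds."""
    aic_total = bic_total = 0
    n_trials = 0
    for seed in range(8):
        tab = _cohort_with_truth(
            (Term("sex", transform="categorical"), Term("ggt", transform="log", center=3.27)),
            {"sex[male]": 0.3, "ggt": 0.3},
            n=4000,
            seed=100 + seed,
        )
        spec = RPModelSpec(
            baseline_df=1,
            terms=(Term("sex", transform="categorical"), Term("ggt", transform="log", center=3.27)),
        )
        kept_aic = select_interactions(tab, spec, "ggt", SelectionConfig(criterion="AIC"))
        kept_bic = select_interactions(tab, spec, "ggt", SelectionConfig(criterion="BIC"))
        aic_total += len(kept_aic.by) + (kept_aic.time_df > 0)
        bic_total += len(kept_bic.by) + (kept_bic.time_df > 0)
        n_trials += 4
    # AIC false-selection probability per 1-df partner is ~0.157, per 2-df ~0.135;
    # with 32 partner trials the count should stay well below half
    assert aic_total <= 0.45 * n_trials
    assert bic_total <= aic_total


def test_scenario_specs_nest():
    specs = build_scenario_specs()
    vars_of = lambda s: {t.var for t in s.terms}
    assert vars_of(specs[2]) <= vars_of(specs[4])
    assert vars_of(specs[3]) <= vars_of(specs[4])
    assert vars_of(specs[1]) <= vars_of(specs[2]) and vars_of(specs[1]) <= vars_of(specs[3])
    # scenario 1 carries no blood or spirometry terms
    assert vars_of(specs[1]).isdisjoint(set(BLOOD_VARS) | set(SPIRO_VARS))
    # term tuples themselves nest
    assert set(specs[2].terms) <= set(specs[4].terms)
    assert set(specs[3].terms) <= set(specs[4].terms)


def test_published_preset_rows():
    """The preset encodes the published selected specification: bilirubin
    log + sex + 2-df timescale; FEV1 linear with a 3-df spline; urate log +
    sex + smoking status."""
    bil = PUBLISHED_TERMS["bilirubin"]
    assert bil.transform == "log" and bil.by == ("sex",) and bil.time_df == 2
    fev = PUBLISHED_TERMS["fev1"]
    assert fev.transform == "linear" and fev.spline_df == 3 and not fev.by
    ur = PUBLISHED_TERMS["urate"]
    assert ur.transform == "log" and set(ur.by) == {"sex", "smoking_status"} and ur.time_df == 0


def test_split_sample_disjoint():
    sel, rest = split_indices(1001, 0.5, seed=4)
    assert len(np.intersect1d(sel, rest)) == 0
    assert len(sel) + len(rest) == 1001
    tab = pd.DataFrame({"x": np.arange(20)})
    cfg = SelectionConfig(sample_mode="split", split_fraction=0.3, seed=1)
    a = selection_sample(tab, cfg)
    b = fitting_sample(tab, cfg)
    assert set(a["x"]).isdisjoint(set(b["x"]))
    assert len(a) + len(b) == 20


def test_selection_config_validation():
    with pytest.raises(ValueError):
        SelectionConfig(criterion="AICC")
    with pytest.raises(ValueError):
        SelectionConfig(sample_mode="split", split_fraction=1.5)


def test_bic_formula_uses_events_by_default():
    tab = _cohort_with_truth((), {}, n=2000, seed=9)
    f = fit(tab, RPModelSpec(baseline_df=1, terms=()))
    bic = criterion_value(f, SelectionConfig(criterion="BIC"))
    assert bic == pytest.approx(-2 * f.loglik + np.log(f.n_events) * f.df_model)
    bic_rows = criterion_value(f, SelectionConfig(criterion="BIC", bic_n="rows"))
    assert bic_rows == pytest.approx(-2 * f.loglik + np.log(f.n_used) * f.df_model)
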