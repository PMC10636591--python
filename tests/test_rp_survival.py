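"""Royston-Parmar model: likelihood closed forms, fitting, prediction, LR tests."""

import json

import numpy as np
import pandas as pd
import pytest

from lcrisk.rp_survival import (
    RPFit,
    RPModelSpec,
    Term,
    complete_cases,
    fit,
    log_likelihood,
    lr_test,
    predict_risk,
)

WEIBULL = RPModelSpec(baseline_df=1)


def test_loglik_single_event_closed_form():
    """Weibull with gamma=(0,1): H(1)=1, h(1)=1, so an event at t=1 gives
    l = ln h(1) - H(1) = -1."""
    df = pd.DataFrame({"time": [1.0], "event": [1]})
    assert log_likelihood(np.array([0.0, 1.0]), df, WEIBULL) == pytest.approx(-1.0)


def test_loglik_single_censored_closed_form():
    """A censored subject contributes -H(t): here -exp(0) = -1."""
    df = pd.DataFrame({"time": [1.0], "event": [0]})
    assert log_likelihood(np.array([0.0, 1.0]), df, WEIBULL) == pytest.approx(-1.0)


def test_null_coefficient_leaves_loglik_unchanged():
    df = pd.DataFrame({"time": [0.5, 1.0, 2.0], "event": [1, 0, 1], "fev1": [2.0, 3.0, 2.5]})
    base = log_likelihood(np.array([0.2, 1.1]), df, WEIBULL)
    spec = RPModelSpec(baseline_df=1, terms=(Term("fev1"),))
    with_cov = log_likelihood(np.array([0.2, 1.1, 0.0]), df, spec)
    assert with_cov == pytest.approx(base, abs=1e-12)


def test_nonmonotone_hazard_reports_minus_inf():
    df = pd.DataFrame({"time": [1.0], "event": [1]})
    assert log_likelihood(np.array([0.0, -1.0]), df, WEIBULL) == -np.inf


def test_missing_covariate_raises():
    df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 0], "fev1": [2.0, np.nan]})
    spec = RPModelSpec(baseline_df=1, terms=(Term("fev1"),))
    with pytest.raises(ValueError, match="complete"):
        log_likelihood(np.zeros(3), df, spec)


def test_weibull_fit_matches_lifelines_mle(exponential_survival):
    """With a 1-df baseline the model is exactly Weibull; the maximised
    log likelihood must match an independent Weibull MLE."""
    from lifelines import WeibullFitter

    f = fit(exponential_survival, WEIBULL)
    wf = WeibullFitter().fit(
        exponential_survival["time"].to_numpy(), exponential_survival["event"].to_numpy()
    )
    assert f.converged
    assert f.loglik == pytest.approx(wf.log_likelihood_, abs=1e-6)


def test_exponential_parameter_recovery(exponential_survival):
    """Data from hazard e^-5 (shape 1): gamma estimates within 3 SEs."""
    f = fit(exponential_survival, WEIBULL)
    assert abs(f.coef("const") - (-5.0)) < 3 * f.se("const")
    assert abs(f.coef("lnt_0") - 1.0) < 3 * f.se("lnt_0")


def test_binary_covariate_log_hr_recovery():
    rng = np.random.default_rng(3)
    n = 20_000
    x = (rng.uniform(size=n) < 0.5).astype(float)
    lam = np.exp(-5.0 + 0.7 * x)
    t = rng.exponential(1 / lam)
    time = np.minimum(t, 7.0)
    df = pd.DataFrame({"time": time, "event": (t <= 7.0).astype(int), "fev1": x})
    f = fit(df, RPModelSpec(baseline_df=1, terms=(Term("fev1"),)))
    assert f.converged
    assert abs(f.coef("fev1") - 0.7) < 3 * f.se("fev1")


def test_refit_is_bit_stable(exponential_survival):
    f1 = fit(exponential_survival, WEIBULL)
    f2 = fit(exponential_survival, WEIBULL)
    np.testing.assert_array_equal(f1.params, f2.params)


def test_predict_risk_weibull_closed_form():
    """gamma=(-3,1), no covariates: risk(6) = 1 - exp(-6 e^-3) = 0.2582."""
    df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 0]})
    f = fit(df, WEIBULL)
    f.params[:] = [-3.0, 1.0]
    r = predict_risk(f, df.iloc[:1], 6.0)
    assert r[0] == pytest.approx(1 - np.exp(-6 * np.exp(-3.0)), abs=1e-12)
    # risk vanishes as t -> 0+
    assert predict_risk(f, df.iloc[:1], 1e-10)[0] < 1e-9
    with pytest.raises(ValueError):
        predict_risk(f, df.iloc[:1], 0.0)


def test_proportional_hazards_identity():
    """Two subjects differing by beta*dx = 0.7 have log(-log(1-risk))
    differing by exactly 0.7 at every horizon."""
    rng = np.random.default_rng(5)
    n = 4000
    x = rng.normal(size=n)
    lam = np.exp(-2.0 + 0.7 * x)
    t = rng.exponential(1 / lam)
    df = pd.DataFrame({"time": np.minimum(t, 7.0), "event": (t <= 7.0).astype(int), "fev1": x})
    f = fit(df, RPModelSpec(baseline_df=2, terms=(Term("fev1"),)))
    pair = pd.DataFrame({"time": [1.0, 1.0], "event": [1, 1], "fev1": [0.0, 1.0]})
    beta = f.coef("fev1")
    for horizon in (0.5, 2.0, 6.0):
        r = predict_risk(f, pair, horizon)
        cloglog = np.log(-np.log(1 - r))
        assert cloglog[1] - cloglog[0] == pytest.approx(beta, abs=1e-9)


def test_affine_invariance_of_fit():
    """Recentring/rescaling a covariate leaves loglik and risks unchanged."""
    rng = np.random.default_rng(7)
    n = 5000
    x = rng.normal(90, 13, size=n)
    lam = np.exp(-6.0 + 0.02 * (x - 90))
    t = rng.exponential(1 / lam)
    df = pd.DataFrame({"time": np.minimum(t, 7.0), "event": (t <= 7.0).astype(int), "waist": x})
    spec = RPModelSpec(baseline_df=1, terms=(Term("waist"),))
    f1 = fit(df, spec)
    df2 = df.assign(waist=(df["waist"] - 90.0) / 13.0)
    f2 = fit(df2, spec)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
    r1 = predict_risk(f1, df.iloc[:50], 6.0)
    r2 = predict_risk(f2, df2.iloc[:50], 6.0)
    np.testing.assert_allclose(r1, r2, atol=1e-8)
    assert f2.coef("waist") == pytest.approx(13.0 * f1.coef("waist"), rel=1e-6)


def test_risks_bounded_and_monotone_in_horizon(default_cohort):
    from lcrisk.model_selection import CONVENTIONAL_TERMS

    spec = RPModelSpec(baseline_df=3, terms=CONVENTIONAL_TERMS)
    data = complete_cases(default_cohort, spec)
    f = fit(data, spec)
    assert f.converged and f.monotone_ok
    sub = data.iloc[:200]
    r2 = predict_risk(f, sub, 2.0)
    r6 = predict_risk(f, sub, 6.0)
    assert np.all((r2 > 0) & (r6 < 1))
    assert np.all(r6 >= r2)


def _dummy_fit(loglik: float, df_model: int) -> RPFit:
    return RPFit(
        resolved=None, params=np.zeros(1), param_names=["const"], loglik=loglik,
        df_model=df_model, n_used=100, n_events=10, converged=True, n_iter=1,
    )


def test_lr_test_reference_values():
    # identical fits
    chi2, ddf, p = lr_test(_dummy_fit(-50.0, 3), _dummy_fit(-50.0, 3))
    assert (chi2, p) == (0.0, 1.0)
    # chi2 = 3.84 on 1 df sits at the 5 % point
    chi2, ddf, p = lr_test(_dummy_fit(-50.0, 3), _dummy_fit(-50.0 + 3.84 / 2, 4))
    assert p == pytest.approx(0.0500, abs=5e-4)
    # a 217-point improvement on 46 df is overwhelming
    chi2, ddf, p = lr_test(_dummy_fit(-500.0, 24), _dummy_fit(-500.0 + 217 / 2, 70))
    assert p < 1e-20


def test_lr_test_requires_same_sample():
    a = _dummy_fit(-50.0, 3)
    b = RPFit(resolved=None, params=np.zeros(1), param_names=["const"], loglik=-45.0,
              df_model=5, n_used=99, n_events=10, converged=True, n_iter=1)
    with pytest.raises(ValueError, match="sample"):
        lr_test(a, b)


def test_complete_cases_exact_rows(default_cohort):
    spec = RPModelSpec(baseline_df=1, terms=(Term("albumin"), Term("fev1")))
    cc = complete_cases(default_cohort, spec)
    mask = default_cohort[["albumin", "fev1"]].notna().all(axis=1)
    assert len(cc) == int(mask.sum())
    assert not cc[["albumin", "fev1"]].isna().any().any()


def test_fit_serialisation_roundtrip(exponential_survival):
    f = fit(exponential_survival, WEIBULL)
    payload = json.loads(f.to_json())
    assert payload["converged"] is True
    np.testing.assert_allclose(payload["params"], f.params)
    assert payload["df_model"] == f.df_model
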