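"""Synthetic UK-Biobank-like cohorts for lung-cancer risk modelling.

Generates one row per participant: demographics, smoking and medical
histories, blood measurements (liver panel + urate), spirometry, follow-up
time and a lung-cancer event indicator. Marginal covariate distributions are
matched to the published baseline characteristics of the cohort the analysis
emulates (medians/IQRs for skewed variables, means/SDs for symmetric ones,
category frequencies for discrete ones); right-skewed blood measurements are
log-normal with log-scale location/spread solved from the median and IQR.
Correlation structure is a deliberately small set of explicit dependencies
(pack-years only for smokers; FEV1 declining in age and pack-years; FVC =
FEV1 / a ratio centred at 0.75) rather than a full copula.

Event times are drawn from a user-specified Royston-Parmar hazard
(``true_model`` + coefficient values) by inverse-transform sampling: with
U ~ Uniform(0,1), solve eta(ln T | x) = ln(-ln U) on the log-cumulative-hazard
scale — closed form for a Weibull baseline without time-dependent terms,
vectorised bisection otherwise. Censoring is administrative (entry uniform
over a 4-year recruitment window, one fixed end date) plus an independent
exponential death process, giving a ~7-year median follow-up and an event
fraction near 0.5 %.

Missingness is injected MCAR per variable at configured rates; follow-up
time and the event indicator are never missing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from lcrisk.rp_survival import RPModelSpec, ResolvedModel, ResolvedTerm, Term
from lcrisk.splines import SplineSpec, time_basis

# Data-coding conventions shared with the modelling modules.
BOOL_VARS = (
    "family_history_lung_cancer",
    "history_cancer",
    "asthma",
    "allergy",
    "tuberculosis",
    "pneumonia",
    "emphysema",
    "asbestos_exposure",
)

COLUMNS = (
    "id",
    "age_entry",
    "sex",
    "ethnicity",
    "smoking_status",
    "pack_years",
    "alcohol_status",
    "townsend",
    "waist",
    "fev1",
    "fvc",
    "bilirubin",
    "albumin",
    "alt",
    "ast",
    "alp",
    "ggt",
    "urate",
    *BOOL_VARS,
    "time",
    "event",
)


class ConfigError(ValueError):
    """Invalid generator configuration (probabilities, hazards, rates)."""


def _lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a log-normal with the given median and IQR."""
    z75 = 0.6744897501960817
    return float(np.log(median)), float((np.log(q3) - np.log(q1)) / (2 * z75))


def _quantile_curve(points: dict[float, float]):
    """Piecewise-linear quantile function through {prob: value} anchors."""
    ps = np.array(sorted(points))
    vs = np.array([points[p] for p in ps])
    return lambda u: np.interp(u, ps, vs)


def default_true_model() -> tuple[RPModelSpec, dict[str, float]]:
    """The default data-generating hazard: Weibull-like baseline with log,
    interaction and time-dependent covariate effects.

    Coefficients are keyed by design-column name. The intercept is calibrated
    so that the default cohort shows roughly a 0.5 % event fraction over a
    median seven-year follow-up.
    """
    spec = RPModelSpec(
        baseline_df=1,
        terms=(
            Term("age_entry"),
            Term("sex", transform="categorical"),
            Term("ethnicity", transform="categorical"),
            Term("smoking_status", transform="categorical"),
            Term("pack_years", transform="log1p"),
            Term("townsend"),
            Term("family_history_lung_cancer"),
            Term("history_cancer"),
            Term("asthma"),
            Term("allergy"),
            Term("tuberculosis"),
            Term("pneumonia"),
            Term("emphysema"),
            Term("asbestos_exposure"),
            Term("fev1"),
            Term("bilirubin", transform="log", by=("sex",), time_df=1, center=2.0919),
            Term("urate", transform="log", by=("smoking_status",), center=5.7134),
        ),
    )
    coeffs = {
        "const": -13.55,
        "lnt_0": 1.1,
        "age_entry": 0.062,
        "sex[male]": 0.25,
        "ethnicity[Asian]": -0.8,
        "ethnicity[Black]": -0.8,
        "ethnicity[Mixed]": -0.3,
        "ethnicity[Other]": -0.5,
        "smoking_status[former]": 0.9,
        "smoking_status[current]": 1.9,
        "pack_years": 0.24,
        "townsend": 0.06,
        "family_history_lung_cancer": 0.5,
        "history_cancer": 0.35,
        "asthma": 0.05,
        "allergy": -0.2,
        "tuberculosis": 0.4,
        "pneumonia": 0.3,
        "emphysema": 0.55,
        "asbestos_exposure": 0.3,
        "fev1": -0.35,
        "bilirubin": -0.35,
        "bilirubin:sex[male]": -0.12,
        "bilirubin:lnt_0": -0.06,
        "urate": 0.45,
        "urate:smoking_status[former]": 0.25,
        "urate:smoking_status[current]": 0.45,
    }
    return spec, coeffs


def recovery_truth() -> tuple[RPModelSpec, dict[str, float]]:
    """A data-generating model for parameter-recovery studies: log effects,
    a covariate spline, categorical interactions and a 2-df time-dependent
    effect, all with explicit knots so the fitted model is exactly the
    generating one. The intercept targets roughly a 5 % event fraction
    (about 1,000 events at n = 20,000) so coefficient recovery is informative
    at moderate sample sizes."""
    ln = np.log
    spec = RPModelSpec(
        baseline_df=1,
        terms=(
            Term("age_entry", spline_df=2, knots=(45.0, 58.0, 68.0)),
            Term("sex", transform="categorical"),
            Term("smoking_status", transform="categorical"),
            Term("pack_years", transform="log1p"),
            Term("fev1"),
            Term(
                "bilirubin",
                transform="log",
                by=("sex",),
                time_df=2,
                time_knots=(ln(0.3), ln(2.5), ln(7.5)),
                center=2.0919,
            ),
            Term("urate", transform="log", by=("smoking_status",), center=5.7134),
        ),
    )
    coeffs = {
        "const": -11.05,
        "lnt_0": 1.1,
        "age_entry": 0.06,
        "age_entry_s1": 0.03,
        "sex[male]": 0.3,
        "smoking_status[former]": 0.9,
        "smoking_status[current]": 1.8,
        "pack_years": 0.25,
        "fev1": -0.3,
        "bilirubin": -0.4,
        "bilirubin:sex[male]": -0.15,
        "bilirubin:lnt_0": -0.08,
        "bilirubin:lnt_1": 0.10,
        "urate": 0.4,
        "urate:smoking_status[former]": 0.3,
        "urate:smoking_status[current]": 0.5,
    }
    return spec, coeffs


def recovery_config(seed: int, n: int = 20_000) -> GeneratorConfig:
    """Generator configuration for the parameter-recovery study."""
    spec, coeffs = recovery_truth()
    return GeneratorConfig(
        n_participants=n, seed=seed, true_model=spec, true_coeffs=coeffs
    )


def _default_covariate_params() -> dict:
    return {
        "sex_p_male": 0.456,
        "age_quantiles": {0.0: 40.0, 0.25: 50.6, 0.5: 58.3, 0.75: 63.7, 1.0: 70.0},
        "ethnicity_p": {"White": 0.941, "Asian": 0.023, "Black": 0.016, "Mixed": 0.006, "Other": 0.009},
        "smoking_p": {"never": 0.545, "former": 0.344, "current": 0.105},
        "alcohol_p": {"never": 0.045, "previous": 0.036, "current": 0.916},
        "pack_years_median_iqr": (19.0, 10.0, 32.0),
        "townsend_quantiles": {0.0: -6.5, 0.25: -3.6, 0.5: -2.1, 0.75: 0.5, 1.0: 11.0},
        "waist_mean_sd": (90.3, 13.5),
        # FEV1 (litres): sex-specific level minus age and pack-year decline
        "fev1": {"male": 3.25, "female": 2.48, "age_slope": -0.030, "py_slope": -0.006, "sd": 0.55},
        # ratio declines with age and smoking so airway obstruction concentrates
        # in the screening-eligible group, as spirometry programmes observe
        "fev1_fvc_ratio": {"base": 0.76, "age_slope": -0.0015, "py_slope": -0.0008, "sd": 0.055},
        "ast_alt_log_corr": 0.75,
        "blood_median_iqr": {
            "bilirubin": (8.1, 6.4, 10.4),
            "albumin": (45.2, 43.5, 46.9),
            "alt": (20.1, 15.4, 27.4),
            "ast": (24.4, 21.0, 28.8),
            "alp": (80.4, 67.2, 95.9),
            "ggt": (26.3, 18.5, 40.9),
            "urate": (302.9, 250.4, 360.8),
        },
        "history_p": {
            "family_history_lung_cancer": 0.124,
            "history_cancer": 0.105,
            "asthma": 0.124,
            "allergy": 0.243,
            "tuberculosis": 0.005,
            "pneumonia": 0.014,
            "emphysema": 0.024,
            # asbestos prevalence is not published for this cohort; generator default
            "asbestos_exposure": 0.05,
        },
    }


def _default_missingness() -> dict[str, float]:
    # published missing-data percentages; FVC shares the spirometry visit with FEV1
    return {
        "waist": 0.004,
        "smoking_status": 0.006,
        "alcohol_status": 0.003,
        "townsend": 0.001,
        "ethnicity": 0.006,
        "alp": 0.065,
        "alt": 0.066,
        "ast": 0.069,
        "ggt": 0.066,
        "bilirubin": 0.069,
        "urate": 0.067,
        "albumin": 0.144,
        "fev1": 0.097,
        "fvc": 0.097,
    }


@dataclass
class CensoringParams:
    """Administrative window: entry uniform over ``recruitment_span`` years
    with a fixed end date ``min_followup`` years after the last entry, plus
    independent exponential death censoring."""

    min_followup: float = 5.1
    recruitment_span: float = 4.0
    death_rate: float = 0.007  # per year

    def validate(self) -> None:
        if self.min_followup <= 0 or self.recruitment_span < 0 or self.death_rate < 0:
            raise ConfigError("invalid censoring parameters")


@dataclass
class GeneratorConfig:
    n_participants: int = 50_000
    seed: int = 0
    covariate_params: dict = field(default_factory=_default_covariate_params)
    missingness_rates: dict[str, float] = field(default_factory=_default_missingness)
    true_model: RPModelSpec | None = None
    true_coeffs: dict[str, float] | None = None
    censoring: CensoringParams = field(default_factory=CensoringParams)

    def __post_init__(self) -> None:
        if self.true_model is None or self.true_coeffs is None:
            spec, coeffs = default_true_model()
            self.true_model = self.true_model or spec
            self.true_coeffs = self.true_coeffs or coeffs
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        for key in ("ethnicity_p", "smoking_p", "alcohol_p"):
            probs = np.array(list(self.covariate_params[key].values()))
            if np.any(probs < 0) or np.any(probs > 1):
                raise ConfigError(f"{key} outside [0,1]")
        for var, r in self.missingness_rates.items():
            if not 0 <= r <= 1:
                raise ConfigError(f"missingness rate for {var} outside [0,1]: {r}")
        if not all(np.isfinite(list(self.true_coeffs.values()))):
            raise ConfigError("true model coefficients must be finite")
        self.censoring.validate()


# ---------------------------------------------------------------------------
# covariate draws


def _draw_covariates(rng: np.random.Generator, n: int, cp: dict) -> pd.DataFrame:
    def cat(pdict):
        labels = list(pdict)
        probs = np.array([pdict[k] for k in labels], dtype=float)
        probs = probs / probs.sum()
        return rng.choice(labels, size=n, p=probs)

    df = pd.DataFrame({"id": np.arange(1, n + 1)})
    df["age_entry"] = _quantile_curve(cp["age_quantiles"])(rng.uniform(size=n)).round(1)
    df["sex"] = np.where(rng.uniform(size=n) < cp["sex_p_male"], "male", "female")
    df["ethnicity"] = cat(cp["ethnicity_p"])
    df["smoking_status"] = cat(cp["smoking_p"])
    df["alcohol_status"] = cat(cp["alcohol_p"])

    m, q1, q3 = cp["pack_years_median_iqr"]
    mu, sig = _lognormal_from_median_iqr(m, q1, q3)
    py = np.exp(rng.normal(mu, sig, size=n))
    df["pack_years"] = np.where(df["smoking_status"] == "never", 0.0, np.round(py, 1))

    df["townsend"] = _quantile_curve(cp["townsend_quantiles"])(rng.uniform(size=n)).round(2)
    wm, ws = cp["waist_mean_sd"]
    df["waist"] = np.clip(rng.normal(wm, ws, size=n), 55.0, None).round(1)

    f = cp["fev1"]
    base = np.where(df["sex"] == "male", f["male"], f["female"])
    fev1 = (
        base
        + f["age_slope"] * (df["age_entry"].to_numpy() - 58.0)
        + f["py_slope"] * df["pack_years"].to_numpy()
        + rng.normal(0.0, f["sd"], size=n)
    )
    df["fev1"] = np.clip(fev1, 0.3, None).round(2)
    fr = cp["fev1_fvc_ratio"]
    ratio = (
        fr["base"]
        + fr["age_slope"] * (df["age_entry"].to_numpy() - 58.0)
        + fr["py_slope"] * df["pack_years"].to_numpy()
        + rng.normal(0.0, fr["sd"], size=n)
    )
    ratio = np.clip(ratio, 0.45, 0.92)
    df["fvc"] = (df["fev1"] / ratio).round(2)

    # ALT and AST share a latent log-scale factor (they track each other
    # clinically); the other assays are drawn independently
    rho = cp["ast_alt_log_corr"]
    z_alt = rng.normal(size=n)
    z_ast = rho * z_alt + np.sqrt(1 - rho**2) * rng.normal(size=n)
    for var, (m, q1, q3) in cp["blood_median_iqr"].items():
        mu, sig = _lognormal_from_median_iqr(m, q1, q3)
        if var == "alt":
            df[var] = np.exp(mu + sig * z_alt).round(1)
        elif var == "ast":
            df[var] = np.exp(mu + sig * z_ast).round(1)
        else:
            df[var] = np.exp(rng.normal(mu, sig, size=n)).round(1)

    for var, p in cp["history_p"].items():
        df[var] = (rng.uniform(size=n) < p).astype(int)
    return df


# ---------------------------------------------------------------------------
# event-time sampling from the true hazard


def _resolve_explicit(spec: RPModelSpec) -> ResolvedModel:
    """Resolve a true-model spec whose knots must all be stated explicitly
    (there is no data to place default knots from)."""
    if spec.baseline_df > 1 and spec.baseline_knots is None:
        raise ConfigError("true model with baseline_df>1 needs explicit baseline_knots")
    baseline = SplineSpec(spec.baseline_knots) if spec.baseline_df > 1 else None
    rterms = []
    for t in spec.terms:
        rcs = None
        if t.spline_df >= 2:
            if t.knots is None:
                raise ConfigError(f"true-model spline term {t.var!r} needs explicit knots")
            rcs = SplineSpec(t.knots)
        tvc = None
        if t.time_df >= 2:
            if t.time_knots is None:
                raise ConfigError(f"true-model tvc term {t.var!r} needs explicit time_knots")
            tvc = SplineSpec(t.time_knots)
        rterms.append(ResolvedTerm(t, rcs, tvc))
    return ResolvedModel(spec, baseline, tuple(rterms))


def _theta_from_coeffs(rm: ResolvedModel, covs: pd.DataFrame, coeffs: dict[str, float]) -> np.ndarray:
    probe = covs.iloc[:1].copy()
    _, _, names = rm.design_at(probe, np.array([0.0]))
    unknown = set(coeffs) - set(names)
    if unknown:
        raise ConfigError(f"true-model coefficients for unknown columns: {sorted(unknown)}")
    return np.array([coeffs.get(nm, 0.0) for nm in names]), names


def _check_monotone(rm: ResolvedModel, theta, names, covs, l_lo=-30.0, l_hi=6.0) -> None:
    """Reject hazards whose log-cumulative-hazard is not increasing in log
    time for every subject (non-invertible cumulative hazard)."""
    grid = np.linspace(l_lo, l_hi, 257)
    ng = rm.n_gamma
    _, Bd = time_basis(grid, rm.baseline_spec)
    base = Bd @ theta[1:ng]
    worst = base.copy()
    pos = ng + rm.static_design(covs.iloc[:1])[0].shape[1]
    for z, tspec, ncol, _ in rm.tvc_blocks(covs):
        _, Td = time_basis(grid, tspec)
        val = Td @ theta[pos : pos + ncol]
        lo, hi = float(z.min()), float(z.max())
        worst += np.minimum(val * lo, val * hi)
        pos += ncol
    if np.any(worst <= 0):
        raise ConfigError(
            "true hazard is non-invertible: d eta/d ln t <= 0 for some subject/time; "
            "reduce time-dependent coefficients or baseline slope"
        )


def _sample_event_times(rng, rm: ResolvedModel, theta, covs: pd.DataFrame) -> np.ndarray:
    n = len(covs)
    u = rng.uniform(size=n)
    target = np.log(-np.log(u))  # solve eta(ln T) = ln(-ln U)
    ng = rm.n_gamma
    S, _ = rm.static_design(covs)
    p = S.shape[1]
    offset = theta[0] + S @ theta[ng : ng + p]
    tvc = rm.tvc_blocks(covs)
    if rm.baseline_spec is None and not tvc:
        return np.exp((target - offset) / theta[1])  # Weibull closed form
    names = None
    _check_monotone(rm, theta, names, covs)

    def eta(l_vec):
        Bt, _ = time_basis(l_vec, rm.baseline_spec)
        e = offset + Bt @ theta[1:ng]
        pos = ng + p
        for z, tspec, ncol, _ in tvc:
            Tb, _ = time_basis(l_vec, tspec)
            e = e + z * (Tb @ theta[pos : pos + ncol])
            pos += ncol
        return e

    lo = np.full(n, -30.0)
    hi = np.full(n, 6.0)
    beyond = eta(hi) < target  # event later than ~400 years: treat as never
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        below = eta(mid) < target
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    t = np.exp(0.5 * (lo + hi))
    t[beyond] = np.inf
    return t


def generate(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a complete cohort table (no missingness injected yet).

    Deterministic: the same config and seed give a byte-identical table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    covs = _draw_covariates(rng, config.n_participants, config.covariate_params)
    rm = _resolve_explicit(config.true_model)
    theta, _ = _theta_from_coeffs(rm, covs, config.true_coeffs)
    t_event = _sample_event_times(rng, rm, theta, covs)

    cz = config.censoring
    admin = rng.uniform(cz.min_followup, cz.min_followup + cz.recruitment_span, size=len(covs))
    if cz.death_rate > 0:
        death = rng.exponential(1.0 / cz.death_rate, size=len(covs))
    else:
        death = np.full(len(covs), np.inf)
    censor = np.minimum(admin, death)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    covs["time"] = np.maximum(time, 1e-4).round(4)
    covs["event"] = event
    return covs[list(COLUMNS)]


def inject_missingness(
    table: pd.DataFrame, rates: dict[str, float], seed: int
) -> pd.DataFrame:
    """Set values missing completely at random, per variable, at the given
    rates. Follow-up time and the event indicator are never touched."""
    out = table.copy()
    rng = np.random.default_rng(seed)
    for var, rate in rates.items():
        if not 0 <= rate <= 1:
            raise ConfigError(f"missingness rate for {var} outside [0,1]: {rate}")
        if var in ("time", "event"):
            raise ConfigError("time/event cannot be made missing")
        if var not in out.columns:
            raise ConfigError(f"unknown variable {var!r}")
        mask = rng.uniform(size=len(out)) < rate
        if mask.any():
            col = out[var]
            if col.dtype.kind in "if":
                out[var] = col.where(~mask, np.nan)
            else:
                out[var] = col.where(~mask, None)
    return out


def generate_with_missingness(config: GeneratorConfig) -> pd.DataFrame:
    """Full generator: covariates + event times, then MCAR injection.

    A sub-seed derived from the master seed drives the missingness pass so
    the complete table and the degraded table are separately reproducible.
    """
    full = generate(config)
    return inject_missingness(full, config.missingness_rates, seed=config.seed + 1_000_003)


# ---------------------------------------------------------------------------
# configuration serialisation (YAML/JSON, explicit seed, no global state)


def _term_to_dict(t: Term) -> dict:
    return {
        "var": t.var, "transform": t.transform, "spline_df": t.spline_df,
        "knots": list(t.knots) if t.knots else None, "by": list(t.by),
        "time_df": t.time_df,
        "time_knots": list(t.time_knots) if t.time_knots else None,
        "center": t.center,
    }


def _term_from_dict(d: dict) -> Term:
    return Term(
        var=d["var"], transform=d.get("transform", "linear"),
        spline_df=d.get("spline_df", 0),
        knots=tuple(d["knots"]) if d.get("knots") else None,
        by=tuple(d.get("by", ())), time_df=d.get("time_df", 0),
        time_knots=tuple(d["time_knots"]) if d.get("time_knots") else None,
        center=d.get("center", 0.0),
    )


def config_to_dict(cfg: GeneratorConfig) -> dict:
    return {
        "n_participants": cfg.n_participants,
        "seed": cfg.seed,
        "covariate_params": cfg.covariate_params,
        "missingness_rates": cfg.missingness_rates,
        "true_model": {
            "baseline_df": cfg.true_model.baseline_df,
            "baseline_knots": list(cfg.true_model.baseline_knots)
            if cfg.true_model.baseline_knots
            else None,
            "terms": [_term_to_dict(t) for t in cfg.true_model.terms],
        },
        "true_coeffs": cfg.true_coeffs,
        "censoring": {
            "min_followup": cfg.censoring.min_followup,
            "recruitment_span": cfg.censoring.recruitment_span,
            "death_rate": cfg.censoring.death_rate,
        },
    }


def config_from_dict(d: dict) -> GeneratorConfig:
    defaults = _default_covariate_params()
    defaults.update(d.get("covariate_params", {}))
    tm = d.get("true_model")
    spec = None
    if tm is not None:
        spec = RPModelSpec(
            baseline_df=tm.get("baseline_df", 1),
            terms=tuple(_term_from_dict(t) for t in tm.get("terms", [])),
            baseline_knots=tuple(tm["baseline_knots"]) if tm.get("baseline_knots") else None,
        )
    cz = d.get("censoring", {})
    return GeneratorConfig(
        n_participants=d.get("n_participants", 50_000),
        seed=d["seed"],  # an explicit seed is mandatory in config files
        covariate_params=defaults,
        missingness_rates=d.get("missingness_rates", _default_missingness()),
        true_model=spec,
        true_coeffs=d.get("true_coeffs"),
        censoring=CensoringParams(
            min_followup=cz.get("min_followup", 5.1),
            recruitment_span=cz.get("recruitment_span", 4.0),
            death_rate=cz.get("death_rate", 0.007),
        ),
    )


def load_config(path) -> GeneratorConfig:
    """Read a generator configuration from a YAML or JSON file."""
    import json
    from pathlib import Path

    import yaml

    text = Path(path).read_text()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return config_from_dict(d)


# ---------------------------------------------------------------------------
# delimited-text I/O (CSV, UTF-8, header row, "NA" for missing)


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="NA")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        na_values=["NA"],
        keep_default_na=False,
        dtype={c: "float64" for c in ("time", "pack_years")},
    )
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file lacks required columns: {sorted(missing)}")
    return df
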