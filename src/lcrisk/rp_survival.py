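"""Royston-Parmar flexible parametric survival model on the log-cumulative-hazard scale.

The model writes the log cumulative hazard of subject i at time t as

    eta_i(t) = s(ln t; gamma) + x_i' beta  [+ sum_v z_vi * s_v(ln t; c_v)]

where s is a restricted cubic spline of log time (the baseline), x_i the
covariate design and the optional z_vi * s_v blocks carry time-dependent
(non-proportional-hazards) effects. With H = exp(eta) the log likelihood is

    l = sum_i { d_i * [ln(d eta_i/d ln t) - ln t_i + eta_i] - exp(eta_i) }

for event indicator d_i. A baseline with 1 df (s = gamma0 + gamma1 ln t)
is exactly the Weibull model. Fitting is by full Newton iteration with
analytic gradient and Hessian from a deterministic Kaplan-Meier-based
initialisation; refitting identical inputs is bit-stable.

Predicted t-year risk is 1 - S(t|x) = 1 - exp(-exp(eta(t, x))).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from lcrisk.splines import SplineSpec, default_knots, rcs_basis, time_basis, time_knots_from_events

# Categorical covariates with their level order; the first level is the
# reference and gets no dummy column.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "smoking_status": ("never", "former", "current"),
    "alcohol_status": ("never", "previous", "current"),
    "ethnicity": ("White", "Asian", "Black", "Mixed", "Other"),
}

_PARTNER_VARS = {"sex": ["sex"], "age": ["age_entry"], "smoking_status": ["smoking_status"]}


@dataclass(frozen=True)
class Term:
    """One covariate term of the model.

    transform: 'linear', 'log', 'log1p' (continuous), or 'categorical'.
    spline_df: if >=2, a restricted cubic spline of that df is applied to the
        transformed value (first spline column is the transformed value itself).
    by: interaction partners among {'sex', 'age', 'smoking_status'}; the
        interaction multiplies the partner columns with the primary
        (pre-spline) transformed column.
    time_df: if >=1, a time-dependent effect: primary column times a
        log-time spline of that df (1 = linear in log time).
    knots / time_knots: explicit knot locations (transformed scale / log-time
        scale); when absent they are placed at Harrell's default percentiles
        of the analysis sample at fit time.
    """

    var: str
    transform: str = "linear"
    spline_df: int = 0
    knots: tuple[float, ...] | None = None
    by: tuple[str, ...] = ()
    time_df: int = 0
    time_knots: tuple[float, ...] | None = None
    center: float = 0.0

    def __post_init__(self) -> None:
        if self.transform not in {"linear", "log", "log1p", "categorical"}:
            raise ValueError(f"unknown transform {self.transform!r}")
        bad = set(self.by) - set(_PARTNER_VARS)
        if bad:
            raise ValueError(f"unknown interaction partners {sorted(bad)}")
        if self.transform == "categorical" and (self.spline_df or self.by or self.time_df):
            raise ValueError("categorical terms support no splines/interactions/tvc")

    def required_columns(self) -> list[str]:
        cols = [self.var]
        for p in self.by:
            cols += _PARTNER_VARS[p]
        return cols


@dataclass(frozen=True)
class RPModelSpec:
    """Model structure: baseline log-time spline df plus covariate terms."""

    baseline_df: int = 3
    terms: tuple[Term, ...] = ()
    baseline_knots: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.baseline_df < 1:
            raise ValueError("baseline_df must be >= 1")
        object.__setattr__(self, "terms", tuple(self.terms))

    def required_columns(self) -> list[str]:
        cols: list[str] = []
        for t in self.terms:
            for c in t.required_columns():
                if c not in cols:
                    cols.append(c)
        return cols


def complete_cases(table: pd.DataFrame, spec: RPModelSpec) -> pd.DataFrame:
    """Rows of ``table`` with no missing value in any variable the spec uses."""
    cols = spec.required_columns()
    if not cols:
        return table
    return table.loc[table[cols].notna().all(axis=1)]


# ---------------------------------------------------------------------------
# design construction


def _primary_column(table: pd.DataFrame, term: Term) -> np.ndarray:
    v = table[term.var].to_numpy(dtype=float)
    if np.any(~np.isfinite(v)):
        raise ValueError(
            f"variable {term.var!r} has missing/non-finite values; filter to complete cases first"
        )
    if term.transform == "linear":
        return v
    if term.transform == "log":
        if np.any(v <= 0):
            raise ValueError(f"log transform of {term.var!r}: non-positive values present")
        return np.log(v)
    if term.transform == "log1p":
        if np.any(v < 0):
            raise ValueError(f"log1p transform of {term.var!r}: negative values present")
        return np.log1p(v)
    raise ValueError(term.transform)


def _dummy_columns(table: pd.DataFrame, var: str) -> tuple[np.ndarray, list[str]]:
    levels = CATEGORICAL_LEVELS[var]
    raw = table[var]
    if raw.isna().any():
        raise ValueError(f"variable {var!r} has missing values; filter to complete cases first")
    vals = raw.astype(str).to_numpy()
    unknown = set(vals) - set(levels)
    if unknown:
        raise ValueError(f"unknown levels {sorted(unknown)} for {var!r}")
    cols = np.column_stack([(vals == lev).astype(float) for lev in levels[1:]])
    return cols, [f"{var}[{lev}]" for lev in levels[1:]]


def _partner_columns(table: pd.DataFrame, partner: str) -> tuple[np.ndarray, list[str]]:
    if partner == "sex":
        cols, _ = _dummy_columns(table, "sex")
        return cols, ["sex[male]"]
    if partner == "age":
        # fixed affine coding keeps the design deterministic across samples
        age = table["age_entry"].to_numpy(dtype=float)
        return ((age - 60.0) / 10.0)[:, None], ["age_c"]
    if partner == "smoking_status":
        return _dummy_columns(table, "smoking_status")
    raise ValueError(partner)


@dataclass(frozen=True)
class ResolvedTerm:
    term: Term
    rcs_spec: SplineSpec | None  # spline of the transformed covariate
    tvc_spec: SplineSpec | None  # log-time spline of the time-dependent block


@dataclass(frozen=True)
class ResolvedModel:
    """Spec with all knot locations pinned to concrete values."""

    spec: RPModelSpec
    baseline_spec: SplineSpec | None
    terms: tuple[ResolvedTerm, ...]

    @property
    def n_gamma(self) -> int:
        return 1 + self.spec.baseline_df

    def static_design(self, table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        """Time-constant design columns: main effects then interactions."""
        blocks: list[np.ndarray] = []
        names: list[str] = []
        for rt in self.terms:
            t = rt.term
            if t.transform == "categorical":
                cols, nm = _dummy_columns(table, t.var)
                blocks.append(cols)
                names += nm
                continue
            z = _primary_column(table, t)
            if rt.rcs_spec is not None:
                B = rcs_basis(z, rt.rcs_spec)
                blocks.append(B)
                names += [t.var] + [f"{t.var}_s{j}" for j in range(1, B.shape[1])]
            else:
                blocks.append(z[:, None])
                names.append(t.var)
            zc = z - t.center
            for p in t.by:
                pc, pn = _partner_columns(table, p)
                blocks.append(pc * zc[:, None])
                names += [f"{t.var}:{n}" for n in pn]
        if blocks:
            return np.column_stack(blocks), names
        return np.empty((len(table), 0)), names

    def tvc_blocks(self, table: pd.DataFrame) -> list[tuple[np.ndarray, SplineSpec | None, int, str]]:
        """Time-dependent blocks: (primary column, log-time spec, n columns, name)."""
        out = []
        for rt in self.terms:
            if rt.term.time_df:
                z = _primary_column(table, rt.term) - rt.term.center
                ncol = 1 if rt.tvc_spec is None else rt.tvc_spec.df
                out.append((z, rt.tvc_spec, ncol, rt.term.var))
        return out

    def n_params(self, table: pd.DataFrame) -> int:
        S, _ = self.static_design(table.iloc[:1])
        q = sum(nc for _, _, nc, _ in self.tvc_blocks(table.iloc[:1]))
        return self.n_gamma + S.shape[1] + q

    def design_at(
        self, table: pd.DataFrame, log_t: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Full design A (for eta) and its log-time derivative D at ``log_t``.

        ``log_t`` is either one value per row or a scalar broadcast to all rows.
        """
        n = len(table)
        log_t = np.broadcast_to(np.asarray(log_t, dtype=float), (n,))
        Bt, Bd = time_basis(log_t, self.baseline_spec)
        S, names = self.static_design(table)
        blocksA = [np.ones((n, 1)), Bt, S]
        blocksD = [np.zeros((n, 1)), Bd, np.zeros_like(S)]
        allnames = (
            ["const"] + [f"lnt_{j}" for j in range(Bt.shape[1])] + names
        )
        for z, tspec, _, nm in self.tvc_blocks(table):
            Tb, Td = time_basis(log_t, tspec)
            blocksA.append(Tb * z[:, None])
            blocksD.append(Td * z[:, None])
            allnames += [f"{nm}:lnt_{j}" for j in range(Tb.shape[1])]
        return np.column_stack(blocksA), np.column_stack(blocksD), allnames


def resolve(spec: RPModelSpec, table: pd.DataFrame) -> ResolvedModel:
    """Pin all knots: baseline/time-dependent knots from uncensored log event
    times, covariate-spline knots at Harrell percentiles of the sample."""
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy()
    if spec.baseline_knots is not None:
        baseline = SplineSpec(spec.baseline_knots) if spec.baseline_df > 1 else None
    else:
        baseline = time_knots_from_events(time, event, spec.baseline_df)
    rterms = []
    for t in spec.terms:
        rcs_spec = None
        if t.spline_df >= 2:
            if t.knots is not None:
                rcs_spec = SplineSpec(t.knots)
            else:
                rcs_spec = default_knots(_primary_column(table, t), t.spline_df)
        tvc_spec = None
        if t.time_df >= 2:
            if t.time_knots is not None:
                tvc_spec = SplineSpec(t.time_knots)
            else:
                lt = np.log(time[event == 1])
                knots = np.percentile(lt, [10, 50, 90] if t.time_df == 2 else [5, 35, 65, 95],
                                      method="linear")
                tvc_spec = SplineSpec(tuple(knots))
        rterms.append(ResolvedTerm(t, rcs_spec, tvc_spec))
    return ResolvedModel(spec, baseline, tuple(rterms))


# ---------------------------------------------------------------------------
# likelihood and fitting


@dataclass
class RPFit:
    """Maximum-likelihood fit of an R-P model."""

    resolved: ResolvedModel
    params: np.ndarray
    param_names: list[str]
    loglik: float
    df_model: int  # free parameters excluding the baseline intercept
    n_used: int
    n_events: int
    converged: bool
    n_iter: int
    vcov: np.ndarray | None = None
    monotone_ok: bool = True  # d eta/d ln t > 0 at all event times post-fit

    @property
    def gamma(self) -> np.ndarray:
        return self.params[: self.resolved.n_gamma]

    @property
    def beta(self) -> np.ndarray:
        return self.params[self.resolved.n_gamma :]

    def coef(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])

    def se(self, name: str) -> float:
        if self.vcov is None:
            raise ValueError("no covariance available")
        i = self.param_names.index(name)
        return float(np.sqrt(self.vcov[i, i]))

    def to_json(self) -> str:
        rm = self.resolved

        def _knots(s: SplineSpec | None):
            return None if s is None else list(s.knots)

        payload = {
            "baseline_df": rm.spec.baseline_df,
            "baseline_knots": _knots(rm.baseline_spec),
            "terms": [
                {
                    "var": rt.term.var,
                    "transform": rt.term.transform,
                    "spline_df": rt.term.spline_df,
                    "knots": _knots(rt.rcs_spec),
                    "by": list(rt.term.by),
                    "time_df": rt.term.time_df,
                    "time_knots": _knots(rt.tvc_spec),
                }
                for rt in rm.terms
            ],
            "params": self.params.tolist(),
            "param_names": self.param_names,
            "loglik": self.loglik,
            "df_model": self.df_model,
            "n_used": self.n_used,
            "n_events": self.n_events,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "monotone_ok": self.monotone_ok,
        }
        return json.dumps(payload, indent=2)


def _loglik_parts(theta, A, D, d, log_t):
    eta = A @ theta
    ds = D @ theta
    ev = d == 1
    if np.any(ds[ev] <= 0):
        return -np.inf, eta, ds
    with np.errstate(over="ignore"):
        He = np.exp(eta)
    if not np.all(np.isfinite(He)):
        return -np.inf, eta, ds
    ll = float(np.sum(np.log(ds[ev]) - log_t[ev] + eta[ev]) - He.sum())
    return ll, eta, ds


def log_likelihood(
    params: np.ndarray, table: pd.DataFrame, spec: RPModelSpec | ResolvedModel
) -> float:
    """Exact R-P log likelihood at ``params`` for the given data and spec.

    Rows whose hazard is non-positive at an event time (d eta/d ln t <= 0)
    make the likelihood -inf; this is reported, never clipped.
    """
    rm = spec if isinstance(spec, ResolvedModel) else resolve(spec, table)
    time = table["time"].to_numpy(dtype=float)
    if np.any(time <= 0):
        raise ValueError("times must be > 0")
    log_t = np.log(time)
    d = table["event"].to_numpy(dtype=int)
    A, D, _ = rm.design_at(table, log_t)
    ll, _, _ = _loglik_parts(np.asarray(params, dtype=float), A, D, d, log_t)
    return ll


def _km_initial_gamma(time, event, rm: ResolvedModel) -> np.ndarray:
    """Least-squares fit of log(-log KM survival) on the time basis at event times."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(time, event)
    et = np.unique(time[event == 1])
    S = km.survival_function_at_times(et).to_numpy()
    n = time.size
    S = np.clip(S, 1.0 / (2 * n), 1 - 1.0 / (2 * n))
    y = np.log(-np.log(S))
    Bt, _ = time_basis(np.log(et), rm.baseline_spec)
    X = np.column_stack([np.ones(et.size), Bt])
    g, *_ = np.linalg.lstsq(X, y, rcond=None)
    # baseline slope in log time must start positive for a valid hazard
    if rm.baseline_spec is None and g[1] <= 0:
        g[1] = 0.5
    return g


def fit(table: pd.DataFrame, spec: RPModelSpec, max_iter: int = 200) -> RPFit:
    """Fit by Newton iteration with backtracking line search.

    Requires complete cases for every spec variable and at least one event.
    Convergence: relative log-likelihood change < 1e-9 and max |gradient|
    < 1e-6 (up to ``max_iter`` iterations); otherwise converged=False.
    """
    time = table["time"].to_numpy(dtype=float)
    if np.any(time <= 0):
        raise ValueError("times must be > 0")
    d = table["event"].to_numpy(dtype=int)
    if d.sum() < 1:
        raise ValueError("need at least one event")
    rm = resolve(spec, table)
    log_t = np.log(time)
    A, D, names = rm.design_at(table, log_t)
    P = A.shape[1]

    theta = np.zeros(P)
    theta[: rm.n_gamma] = _km_initial_gamma(time, d, rm)

    ll, eta, ds = _loglik_parts(theta, A, D, d, log_t)
    if not np.isfinite(ll):
        # fall back to a plainly monotone baseline
        theta[: rm.n_gamma] = 0.0
        theta[0] = np.log(max(d.sum(), 1) / np.sum(time))
        theta[1] = 1.0 if rm.baseline_spec is None else 0.0
        if rm.baseline_spec is not None:
            theta[1] = 1.0
        ll, eta, ds = _loglik_parts(theta, A, D, d, log_t)

    ev = d == 1
    converged = False
    it = 0
    singular = False
    for it in range(1, max_iter + 1):
        He = np.exp(eta)
        w1 = np.zeros_like(ds)
        w1[ev] = 1.0 / ds[ev]
        g = D.T @ w1 + A.T @ (d - He)
        H = -(D * (w1**2)[:, None]).T @ D - (A * He[:, None]).T @ A
        ridge = 0.0
        for _ in range(8):
            try:
                step = np.linalg.solve(-(H - ridge * np.eye(P)), g)
            except np.linalg.LinAlgError:
                singular = True
                step = None
            if step is not None and np.dot(step, g) > 0:
                break
            ridge = 10.0 * ridge if ridge else 1e-6 * (1 + np.abs(np.diag(H)).max())
        else:
            step = g / (1 + np.abs(np.diag(H)).max())
        # backtracking: keep the hazard positive and the likelihood finite
        alpha = 1.0
        for _ in range(60):
            cand = theta + alpha * step
            ll_new, eta_new, ds_new = _loglik_parts(cand, A, D, d, log_t)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            alpha *= 0.5
        else:
            break
        moved = ll_new - ll
        theta, ll, eta, ds = cand, ll_new, eta_new, ds_new
        if abs(moved) < 1e-9 * (abs(ll) + 1.0):
            He = np.exp(eta)
            w1 = np.zeros_like(ds)
            w1[ev] = 1.0 / ds[ev]
            g = D.T @ w1 + A.T @ (d - He)
            if np.max(np.abs(g)) < 1e-6:
                converged = True
                break

    He = np.exp(eta)
    w1 = np.zeros_like(ds)
    w1[ev] = 1.0 / ds[ev]
    H = -(D * (w1**2)[:, None]).T @ D - (A * He[:, None]).T @ A
    try:
        vcov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        vcov = None
        singular = True
    if singular:
        import warnings

        warnings.warn("singular information matrix: possible separation/non-identifiability")

    return RPFit(
        resolved=rm,
        params=theta,
        param_names=names,
        loglik=ll,
        df_model=P - 1,
        n_used=len(table),
        n_events=int(d.sum()),
        converged=converged,
        n_iter=it,
        vcov=vcov,
        monotone_ok=bool(np.all(ds[ev] > 0)),
    )


def predict_risk(
    fit_: RPFit, table: pd.DataFrame, t: float, return_meta: bool = False
):
    """Predicted probability of the event by time ``t`` given covariates.

    Beyond the boundary knots of the baseline the log-cumulative-hazard is
    extrapolated linearly (the natural-spline tail); with ``return_meta`` the
    extrapolation flag is reported alongside.
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    rm = fit_.resolved
    lt = float(np.log(t))
    A, _, _ = rm.design_at(table, lt)
    eta = A @ fit_.params
    risk = 1.0 - np.exp(-np.exp(eta))
    if return_meta:
        extrap = False
        if rm.baseline_spec is not None:
            k = rm.baseline_spec.knots
            extrap = lt < k[0] or lt > k[-1]
        return risk, {"extrapolated": extrap, "t": t}
    return risk


def lr_test(fit_nested: RPFit, fit_full: RPFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested against full: (chi2, delta df, p).

    Both fits must use the identical analysis rows; model comparison on
    different complete-case samples is refused.
    """
    if (fit_nested.n_used, fit_nested.n_events) != (fit_full.n_used, fit_full.n_events):
        raise ValueError(
            "fits use different analysis samples; refit both on the common complete-case rows"
        )
    ddf = fit_full.df_model - fit_nested.df_model
    if ddf < 0:
        raise ValueError("first argument must be the nested model")
    chi2 = max(2.0 * (fit_full.loglik - fit_nested.loglik), 0.0)
    p = float(stats.chi2.sf(chi2, ddf)) if ddf > 0 else (1.0 if chi2 == 0 else 0.0)
    return chi2, ddf, p
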