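"""Functional-form and interaction selection by information criteria.

For each continuous candidate predictor the transform (linear, log, or a
restricted cubic spline of 2 or 3 df) minimising the criterion is chosen,
fitting one model per candidate with every other continuous expansion
variable held at log. Interactions are then selected by forward stepwise
search over the partners (sex, age, smoking status, timescale) in that fixed
order; a partner is kept iff it lowers the criterion. The timescale partner
is a time-dependent effect carried by a 2-df log-time sub-basis.

AIC = -2 loglik + 2 k; BIC = -2 loglik + ln(n) k with k the number of free
parameters excluding the baseline intercept and n, by default, the number of
events (configurable to the number of rows). A split-sample mode performs
selection on a seeded random half, leaving the other half for fitting.

A "published" preset encodes the published selected specification so
downstream stages can bypass the search entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from lcrisk.rp_survival import RPFit, RPModelSpec, Term, fit

#: conventional predictors (Scenario 1)
CONVENTIONAL_TERMS: tuple[Term, ...] = (
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
)

#: expansion blocks
SPIRO_VARS = ("fev1", "waist")
BLOOD_VARS = ("bilirubin", "albumin", "ast", "alp", "alt", "ggt", "urate")

#: the published selected transforms/interactions (the published preset)
PUBLISHED_TERMS: dict[str, Term] = {
    "bilirubin": Term("bilirubin", transform="log", by=("sex",), time_df=2, center=2.0919),
    "albumin": Term("albumin", transform="log"),
    "ast": Term("ast", transform="log", spline_df=2, by=("sex",), time_df=2, center=3.1946),
    "alp": Term("alp", transform="log", by=("sex", "smoking_status"), time_df=2, center=4.3870),
    "alt": Term("alt", transform="log", by=("sex", "smoking_status"), center=3.0007),
    "ggt": Term("ggt", transform="log", by=("sex",), center=3.2696),
    "urate": Term("urate", transform="log", by=("sex", "smoking_status"), center=5.7134),
    "fev1": Term("fev1", transform="linear", spline_df=3),
    "waist": Term("waist", transform="log"),
}

PARTNER_ORDER = ("sex", "age", "smoking_status", "timescale")


@dataclass(frozen=True)
class SelectionConfig:
    criterion: str = "AIC"  # or "BIC"
    candidate_transforms: tuple = (("linear", 0), ("log", 0), ("linear", 2), ("linear", 3))
    candidate_partners: tuple[str, ...] = PARTNER_ORDER
    sample_mode: str = "full"  # or "split"
    split_fraction: float = 0.5
    seed: int = 0
    bic_n: str = "events"  # or "rows"

    def __post_init__(self) -> None:
        if self.criterion not in {"AIC", "BIC"}:
            raise ValueError("criterion must be AIC or BIC")
        if self.sample_mode not in {"full", "split"}:
            raise ValueError("sample_mode must be full or split")
        if self.sample_mode == "split" and not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0,1)")


def criterion_value(fit_: RPFit, config: SelectionConfig) -> float:
    k = fit_.df_model
    if config.criterion == "AIC":
        return -2.0 * fit_.loglik + 2.0 * k
    n = fit_.n_events if config.bic_n == "events" else fit_.n_used
    return -2.0 * fit_.loglik + np.log(n) * k


def split_indices(n: int, fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint (selection, fitting) row indices; no row appears in both."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = int(round(fraction * n))
    return np.sort(perm[:k]), np.sort(perm[k:])


def selection_sample(table: pd.DataFrame, config: SelectionConfig) -> pd.DataFrame:
    if config.sample_mode == "full":
        return table
    sel, _ = split_indices(len(table), config.split_fraction, config.seed)
    return table.iloc[sel]


def fitting_sample(table: pd.DataFrame, config: SelectionConfig) -> pd.DataFrame:
    if config.sample_mode == "full":
        return table
    _, rest = split_indices(len(table), config.split_fraction, config.seed)
    return table.iloc[rest]


def _with_term(base: RPModelSpec, term: Term) -> RPModelSpec:
    terms = tuple(t for t in base.terms if t.var != term.var) + (term,)
    return replace(base, terms=terms)


def select_transform(
    table: pd.DataFrame,
    base_spec: RPModelSpec,
    variable: str,
    config: SelectionConfig,
    trace: list | None = None,
) -> Term:
    """Pick the transform of ``variable`` minimising the criterion.

    Ties break toward fewer parameters; non-converged candidates are
    excluded with a warning.
    """
    data = selection_sample(table, config)
    best: tuple[float, int, Term] | None = None
    for transform, sdf in config.candidate_transforms:
        cand = Term(variable, transform=transform, spline_df=sdf)
        try:
            f = fit(data, _with_term(base_spec, cand))
        except ValueError as e:  # e.g. log of a variable with non-positive values
            warnings.warn(f"candidate {transform}/rcs{sdf} for {variable} infeasible: {e}")
            continue
        if not f.converged:
            warnings.warn(f"candidate {transform}/rcs{sdf} for {variable} did not converge; excluded")
            continue
        val = criterion_value(f, config)
        if trace is not None:
            trace.append(
                {"variable": variable, "stage": "transform",
                 "candidate": f"{transform}+rcs{sdf}" if sdf else transform,
                 "df": f.df_model, "loglik": f.loglik, "criterion": val, "selected": False}
            )
        key = (val, f.df_model)
        if best is None or key < (best[0], best[1]):
            best = (val, f.df_model, cand)
    if best is None:
        raise RuntimeError(f"no candidate transform converged for {variable}")
    if trace is not None:
        for row in trace:
            if row["variable"] == variable and row["stage"] == "transform":
                row["selected"] = row["df"] == best[1] and row["criterion"] == best[0]
    return best[2]


def _add_partner(term: Term, partner: str) -> Term:
    if partner == "timescale":
        return replace(term, time_df=2)
    return replace(term, by=term.by + (partner,))


def select_interactions(
    table: pd.DataFrame,
    spec_with_main: RPModelSpec,
    variable: str,
    config: SelectionConfig,
    trace: list | None = None,
) -> Term:
    """Forward stepwise interaction search for ``variable``'s term.

    Partners are tried in the fixed order sex, age, smoking status,
    timescale; each is kept iff it lowers the criterion.
    """
    data = selection_sample(table, config)
    current = next(t for t in spec_with_main.terms if t.var == variable)
    f = fit(data, spec_with_main)
    best_val = criterion_value(f, config)
    for partner in config.candidate_partners:
        cand = _add_partner(current, partner)
        fc = fit(data, _with_term(spec_with_main, cand))
        if not fc.converged:
            warnings.warn(f"interaction {variable}x{partner} did not converge; excluded")
            continue
        val = criterion_value(fc, config)
        keep = val < best_val
        if trace is not None:
            trace.append(
                {"variable": variable, "stage": "interaction", "candidate": partner,
                 "df": fc.df_model, "loglik": fc.loglik, "criterion": val, "selected": keep}
            )
        if keep:
            current = cand
            spec_with_main = _with_term(spec_with_main, cand)
            best_val = val
    return current


def select_all(
    table: pd.DataFrame,
    variables: tuple[str, ...] = SPIRO_VARS + BLOOD_VARS,
    config: SelectionConfig = SelectionConfig(),
    baseline_df: int = 3,
) -> tuple[dict[str, Term], pd.DataFrame]:
    """Full selection pass over the expansion variables.

    Transform selection holds every *other* continuous expansion variable at
    log; interactions are then searched variable by variable. Returns the
    selected terms and the selection trace.
    """
    trace: list = []
    selected: dict[str, Term] = {}
    for var in variables:
        others = tuple(
            Term(v, transform="log") for v in variables if v != var
        )
        base = RPModelSpec(baseline_df=baseline_df, terms=CONVENTIONAL_TERMS + others)
        selected[var] = select_transform(table, base, var, config, trace)
    for var in variables:
        others = tuple(selected[v] for v in variables if v != var)
        spec = RPModelSpec(
            baseline_df=baseline_df, terms=CONVENTIONAL_TERMS + others + (selected[var],)
        )
        selected[var] = select_interactions(table, spec, var, config, trace)
    return selected, pd.DataFrame(trace)


def build_scenario_specs(
    extra_terms: dict[str, Term] | None = None, baseline_df: int = 3
) -> dict[int, RPModelSpec]:
    """The four nested screening-scenario model specs.

    Scenario 1: conventional predictors. Scenario 2 adds FEV1, alcohol
    status and waist circumference; Scenario 3 adds the liver blood tests
    and urate; Scenario 4 adds everything. ``extra_terms`` supplies the
    selected transform/interaction per expansion variable (default: the
    published preset).
    """
    terms = dict(PUBLISHED_TERMS if extra_terms is None else extra_terms)
    alcohol = Term("alcohol_status", transform="categorical")
    spiro = tuple(terms[v] for v in SPIRO_VARS if v in terms) + (alcohol,)
    blood = tuple(terms[v] for v in BLOOD_VARS if v in terms)
    return {
        1: RPModelSpec(baseline_df=baseline_df, terms=CONVENTIONAL_TERMS),
        2: RPModelSpec(baseline_df=baseline_df, terms=CONVENTIONAL_TERMS + spiro),
        3: RPModelSpec(baseline_df=baseline_df, terms=CONVENTIONAL_TERMS + blood),
        4: RPModelSpec(baseline_df=baseline_df, terms=CONVENTIONAL_TERMS + spiro + blood),
    }
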