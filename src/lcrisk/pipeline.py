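"""End-to-end orchestration: simulate -> select -> fit -> evaluate -> economics.

Everything here is a deterministic function of (cohort table, master seed,
configuration); the CLI and the analysis scripts are thin wrappers. A single
master seed derives the sub-seeds of every stochastic stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lcrisk import model_selection as ms
from lcrisk import rp_survival as rp
from lcrisk import screening_economics as econ
from lcrisk import synthetic_cohort as sc
from lcrisk.performance_metrics import (
    fraction_new_information,
    harrell_c,
    risk_summary,
    shrinkage_factor,
)

SCENARIO_LABELS = {
    1: "1: conventional",
    2: "2: + FEV1 + alcohol + waist",
    3: "3: + liver blood tests + urate",
    4: "4: fully expanded",
}


def simulate(n: int, seed: int, with_missingness: bool = True) -> pd.DataFrame:
    cfg = sc.GeneratorConfig(n_participants=n, seed=seed)
    return sc.generate_with_missingness(cfg) if with_missingness else sc.generate(cfg)


def simulate_to_csv(n: int, seed: int, out_csv, with_missingness: bool = True) -> dict:
    """Simulate and write the cohort plus a provenance record."""
    table = simulate(n, seed, with_missingness)
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    sc.write_cohort(table, out_csv)
    digest = hashlib.sha256(out_csv.read_bytes()).hexdigest()
    prov = {
        "n_participants": n,
        "seed": seed,
        "with_missingness": with_missingness,
        "rows": int(len(table)),
        "events": int(table["event"].sum()),
        "sha256": digest,
    }
    out_csv.with_suffix(".provenance.json").write_text(json.dumps(prov, indent=2))
    return prov


@dataclass
class AnalysisResult:
    fits: dict[int, rp.RPFit]
    performance: pd.DataFrame
    risk_summaries: pd.DataFrame
    economics: pd.DataFrame
    incidental: dict
    selection_trace: pd.DataFrame | None
    n_analysis: int
    n_events: int

    @property
    def all_converged(self) -> bool:
        return all(f.converged for f in self.fits.values())


def analyse_cohort(
    table: pd.DataFrame,
    baseline_df: int = 3,
    horizons: tuple[float, float] = (2.0, 6.0),
    econ_params: econ.EconParams = econ.EconParams(),
    do_selection: bool = False,
    selection_config: ms.SelectionConfig | None = None,
) -> AnalysisResult:
    """Fit the four scenario models on one common complete-case sample and
    derive the performance, risk-distribution and screening-cost tables."""
    trace = None
    extra = None
    if do_selection:
        cfg = selection_config or ms.SelectionConfig()
        sel_table = rp.complete_cases(
            table, ms.build_scenario_specs(baseline_df=baseline_df)[4]
        )
        extra, trace = ms.select_all(sel_table, config=cfg, baseline_df=baseline_df)
    specs = ms.build_scenario_specs(extra, baseline_df=baseline_df)

    # the scenario-4 complete-case rows are the common analysis sample
    data = rp.complete_cases(table, specs[4]).reset_index(drop=True)
    if do_selection and selection_config and selection_config.sample_mode == "split":
        data = ms.fitting_sample(data, selection_config).reset_index(drop=True)
    n_events = int(data["event"].sum())

    null_fit = rp.fit(data, rp.RPModelSpec(baseline_df=baseline_df, terms=()))
    fits = {s: rp.fit(data, spec) for s, spec in specs.items()}

    horizon = econ_params.horizon
    risks = {s: rp.predict_risk(f, data, horizon) for s, f in fits.items()}

    perf_rows = []
    chi2 = {}
    for s, f in fits.items():
        chi2[s], _, _ = rp.lr_test(null_fit, f)
        c, se, ci = harrell_c(data["time"], data["event"], risks[s])
        if s == 1:
            p_vs_ref, fni = np.nan, np.nan
        else:
            _, _, p_vs_ref = rp.lr_test(fits[1], f)
            fni = fraction_new_information(chi2[1], chi2[s])
        perf_rows.append(
            {
                "scenario": SCENARIO_LABELS[s],
                "c_index": c,
                "c_ci_low": ci[0],
                "c_ci_high": ci[1],
                "df": f.df_model,
                "chi2": chi2[s],
                "p_vs_scenario1": p_vs_ref,
                "fni": fni,
                "shrinkage": shrinkage_factor(chi2[s], f.df_model),
                "converged": f.converged,
            }
        )
    performance = pd.DataFrame(perf_rows)

    # screening-eligible subset: risk distributions and the cost model
    elig = econ.eligible(data, econ_params)
    idx = elig.index.to_numpy()
    rs_rows = []
    for s, f in fits.items():
        row = {"scenario": SCENARIO_LABELS[s]}
        for h in horizons:
            r = rp.predict_risk(f, elig, h)
            summ = risk_summary(np.clip(r, 1e-12, 1 - 1e-12))
            row[f"median_risk_{h:g}y_pct"] = summ["median_pct"]
            row[f"iqr_risk_{h:g}y_pct"] = f"{summ['q1_pct']:.2f}-{summ['q3_pct']:.2f}"
        if s == 1:
            row["fni_eligible"] = np.nan
        rs_rows.append(row)
    risk_summaries = pd.DataFrame(rs_rows)

    base_risk = risks[1][idx]
    results = []
    for s in specs:
        inputs = econ.scenario_inputs_from_risks(
            base_risk,
            risks[s][idx],
            elig["time"].to_numpy(),
            elig["event"].to_numpy(),
            econ_params,
            followup_cost_per_patient=econ_params.followup_cost(s),
            label=SCENARIO_LABELS[s],
        )
        try:
            results.append(econ.run_scenario(inputs, econ_params))
        except econ.EconError:
            pass
    economics = econ.results_table(results) if results else pd.DataFrame()

    followup_set = elig.loc[base_risk >= econ_params.risk_threshold]
    incidental = econ.incidental_findings(followup_set) if len(followup_set) else {}

    return AnalysisResult(
        fits=fits,
        performance=performance,
        risk_summaries=risk_summaries,
        economics=economics,
        incidental=incidental,
        selection_trace=trace,
        n_analysis=len(data),
        n_events=n_events,
    )


def write_reports(result: AnalysisResult, outdir) -> list[Path]:
    """Write the four report tables (plus a markdown summary) under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if result.selection_trace is not None:
        p = outdir / "selection_trace.csv"
        result.selection_trace.to_csv(p, index=False)
        written.append(p)
    for name, df in [
        ("performance.csv", result.performance),
        ("risk_summaries.csv", result.risk_summaries),
        ("economics.csv", result.economics),
    ]:
        p = outdir / name
        df.to_csv(p, index=False)
        written.append(p)
    lines = [
        "# Analysis summary",
        "",
        f"Analysis sample: {result.n_analysis} complete-case rows, {result.n_events} events.",
        f"All fits converged: {result.all_converged}.",
        "",
        "## Performance",
        result.performance.to_string(index=False),
        "",
        "## Screening economics",
        result.economics.to_string(index=False) if len(result.economics) else "(no detectable cases)",
    ]
    if result.incidental:
        lines += [
            "",
            "## Incidental findings among follow-up-tested participants",
            f"AST/ALT > 2: {result.incidental['ast_alt_ratio_gt2_pct']:.1f} %",
            f"FEV1/FVC < 0.7 (no prior lung disease): {result.incidental['fev1_fvc_lt07_pct']:.1f} %",
        ]
    p = outdir / "summary.md"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written
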