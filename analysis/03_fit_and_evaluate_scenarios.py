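"""Fit the four scenario models and compare their prognostic information.

Uses the published-specification preset (published transforms/interactions) on
the common complete-case sample; writes the performance table (c-index,
LR chi-square, FNI, shrinkage) and the predicted-risk summaries for the
screening-eligible subset, plus serialised fitted models.
"""

from pathlib import Path

from lcrisk.pipeline import analyse_cohort, write_reports
from lcrisk.synthetic_cohort import read_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    table = read_cohort(RESULTS / "cohort.csv")
    res = analyse_cohort(table)
    write_reports(res, RESULTS)
    for s, f in res.fits.items():
        (RESULTS / f"fit_scenario{s}.json").write_text(f.to_json())

    print(f"analysis sample: {res.n_analysis} rows, {res.n_events} events")
    print(res.performance.round(3).to_string(index=False))
    c1 = res.performance["c_index"].iloc[0]
    c4 = res.performance["c_index"].iloc[3]
    fni = res.performance["fni"].iloc[3]
    print(
        f"\nexpanding from the conventional model raised the c-index "
        f"from {c1:.3f} to {c4:.3f}; the fully expanded model carries "
        f"{100 * fni:.0f} % new prognostic information"
    )
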