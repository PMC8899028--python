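#!/usr/bin/env python
"""Biomarker-stratified progression-free survival.

For each stratification (EGFR status, WES TMB class, CD8 tumor density
split at the top half): Kaplan-Meier curves, the two-group log-rank test,
and the univariate Cox hazard ratio with 95% CI.
"""

from collections import defaultdict
from pathlib import Path

import pandas as pd

from nsclc_biomarkers import SurvivalRecord, cox_univariate, km_estimate, logrank_test
from nsclc_biomarkers.survival import km_curve_frame

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    surv = pd.read_csv(BASE / "cohort" / "survival.tsv", sep="\t")
    strat_cols = [c for c in surv.columns if c not in ("sample_id", "time_months", "event")]
    records = [
        SurvivalRecord(
            sample_id=r["sample_id"],
            time_months=float(r["time_months"]),
            event=bool(r["event"]),
            strata={c: str(r[c]) for c in strat_cols},
        )
        for _, r in surv.iterrows()
    ]
    outdir = BASE / "survival"
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for var in strat_cols:
        groups = defaultdict(list)
        for r in records:
            groups[r.strata[var]].append(r)
        (la, ga), (lb, gb) = sorted(groups.items())
        lr = logrank_test(ga, gb)
        cov = {r.sample_id: float(r.strata[var] == lb) for r in records}
        cox = cox_univariate(records, cov)
        rows.append(
            {
                "stratification": var,
                "groups": f"{lb} vs {la}",
                "logrank_chi2": round(lr.chi_square, 3),
                "logrank_p": lr.p_value,
                "hr": round(cox.hazard_ratio, 3),
                "ci_low": round(cox.ci_low, 3),
                "ci_high": round(cox.ci_high, 3),
            }
        )
        for lab, grp in ((la, ga), (lb, gb)):
            km_curve_frame(km_estimate(grp)).to_csv(
                outdir / f"km_{var}_{lab}.tsv", sep="\t", index=False
            )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "tests.tsv", sep="\t", index=False)
    print("stratified PFS results:")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
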