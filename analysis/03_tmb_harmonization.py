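#!/usr/bin/env python
"""TMB cutoff harmonization and TMB-High proportions by subtype.

Uses EGFR-wildtype samples as the reference population: computes the WES
TMB-Low proportion at the 10 mut/Mb cutoff, quantile-matches it onto the
panel TMB distribution to obtain the panel cutoff, then classifies every
sample on both assays and tabulates TMB-High proportions per subtype.
"""

import json
from pathlib import Path

import pandas as pd

from nsclc_biomarkers import harmonize_cutoff

BASE = Path(__file__).resolve().parent.parent / "results"
WES_CUTOFF = 10.0


def main() -> None:
    cohort = pd.read_csv(BASE / "cohort" / "cohort.tsv", sep="\t")
    wildtype = cohort[cohort["egfr_subtype"] == "wildtype"]
    harm = harmonize_cutoff(
        wildtype["tmb_wes"].tolist(), WES_CUTOFF, wildtype["tmb_panel"].tolist()
    )
    print(
        f"reference n={len(wildtype)}: WES TMB-Low proportion p={harm.p:.3f}; "
        f"harmonized panel cutoff = {harm.panel_cutoff:.1f} mut/Mb"
    )

    cohort["wes_class"] = (cohort["tmb_wes"] >= WES_CUTOFF).map(
        {True: "TMB-High", False: "TMB-Low"}
    )
    cohort["panel_class"] = (cohort["tmb_panel"] >= harm.panel_cutoff).map(
        {True: "TMB-High", False: "TMB-Low"}
    )
    by_subtype = (
        cohort.groupby("egfr_subtype")
        .agg(
            n=("sample_id", "size"),
            mean_tmb_wes=("tmb_wes", "mean"),
            wes_high_pct=("wes_class", lambda s: 100 * (s == "TMB-High").mean()),
            panel_high_pct=("panel_class", lambda s: 100 * (s == "TMB-High").mean()),
        )
        .sort_values("wes_high_pct", ascending=False)
        .round(2)
    )
    outdir = BASE / "tmb"
    outdir.mkdir(parents=True, exist_ok=True)
    by_subtype.to_csv(outdir / "tmb_high_by_subtype.tsv", sep="\t")
    with open(outdir / "harmonization.json", "w") as fh:
        json.dump(
            {"p": harm.p, "panel_cutoff": harm.panel_cutoff, "wes_cutoff": WES_CUTOFF},
            fh,
            indent=2,
        )
    print("\nTMB-High proportion by subtype (descending):")
    print(by_subtype.to_string())


if __name__ == "__main__":
    main()
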