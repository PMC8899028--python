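#!/usr/bin/env python
"""Immune-microenvironment density comparisons.

Compares immune-cell densities (cells/mm²) between EGFR-mutated and
wildtype samples for every cell type × compartment with Welch's t test, and
tabulates TPS tiers by subtype.
"""

from pathlib import Path

import pandas as pd

from nsclc_biomarkers import compare_groups

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = pd.read_csv(BASE / "cohort" / "cohort.tsv", sep="\t")
    mif = pd.read_csv(BASE / "cohort" / "mif_densities.tsv", sep="\t")
    group_of = {
        row.sample_id: "wildtype" if row.egfr_subtype == "wildtype" else "mutated"
        for row in cohort.itertuples()
    }
    mif["egfr_group"] = mif["sample_id"].map(group_of)

    rows = []
    for (cell_type, comp), grp in mif.groupby(["cell_type", "compartment"], sort=True):
        by_group = {g: sub["density"].tolist() for g, sub in grp.groupby("egfr_group")}
        res = compare_groups(by_group, method="auto")
        rows.append(
            {
                "cell_type": cell_type,
                "compartment": comp,
                "method": res.method_used,
                "statistic": round(res.statistic, 3),
                "p": res.p_value,
            }
        )
    table = pd.DataFrame(rows).sort_values("p")
    outdir = BASE / "time"
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "density_comparisons.tsv", sep="\t", index=False)
    print("EGFR mutated vs wildtype density comparisons (Welch t):")
    print(table.to_string(index=False))

    tps = pd.crosstab(cohort["egfr_subtype"], cohort["tps_tier"], normalize="index")
    tps = (100 * tps).round(1)
    tps.to_csv(outdir / "tps_tier_by_subtype.tsv", sep="\t")
    print("\nTPS tier percentages by subtype:")
    print(tps.to_string())


if __name__ == "__main__":
    main()
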