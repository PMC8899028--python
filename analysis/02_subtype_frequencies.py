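#!/usr/bin/env python
"""EGFR subtype frequencies in the simulated cohort.

Re-derives each sample's subtype from its filtered variant calls (never from
the generator's label) and tabulates frequencies over all samples and over
mutated samples only — the cohort-composition analysis.
"""

from collections import defaultdict
from pathlib import Path

import pandas as pd

from nsclc_biomarkers import (
    FilterProfile,
    classify_egfr,
    filter_variants,
    read_variants,
    tabulate_subtype_frequencies,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = pd.read_csv(BASE / "cohort" / "cohort.tsv", sep="\t")
    variants = read_variants(BASE / "cohort" / "variants.tsv")
    reporting = filter_variants(variants, FilterProfile.reporting())

    by_sample = defaultdict(list)
    for v in reporting:
        if v.gene == "EGFR":
            by_sample[v.sample_id].append(v)
    labels = [
        classify_egfr(by_sample.get(sid, [])).label for sid in cohort["sample_id"]
    ]

    outdir = BASE / "subtypes"
    outdir.mkdir(parents=True, exist_ok=True)
    for mode in ("all", "mutated_only"):
        table = tabulate_subtype_frequencies(labels, denominator_mode=mode)
        table.to_csv(outdir / f"frequencies_{mode}.tsv", sep="\t", index=False)
        print(f"\n--- denominator: {mode} (N={table.attrs['denominator']}) ---")
        print(table.to_string(index=False))

    mutated = sum(lab != "wildtype" for lab in labels)
    print(
        f"\nEGFR mutation prevalence: {100 * mutated / len(labels):.1f}% "
        f"({mutated}/{len(labels)})"
    )


if __name__ == "__main__":
    main()
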