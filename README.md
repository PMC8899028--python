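# nsclc-biomarkers

Biomarker analysis for EGFR-subtyped non-small-cell lung cancer (NSCLC)
cohorts, built as a tested, reusable pipeline plus a set of narrative
analysis drivers. It is aimed at computational oncology groups who want the
full chain — somatic variant filtering, EGFR subtype classification, tumor
mutational burden (TMB) with cross-assay cutoff harmonization,
microsatellite instability (MSI) scoring, PD-L1 tumor proportion score
(TPS) tiering, immune-infiltrate density quantification, and
biomarker-stratified progression-free survival (PFS) — as composable,
oracle-tested functions rather than one-off notebook code.

Because matched clinical datasets of this kind are rarely shareable, the
package ships a first-class synthetic-cohort generator that reproduces the
statistical structure the analysis assumes, so every stage is testable end
to end without external data.

## The methods in brief

- **Variant filtering.** An annotated somatic call survives iff allele
  fraction ≥ 5%, maximum population-database frequency ≤ 1.5%, and its
  consequence class is retained. Two profiles: *reporting* (stopgain,
  missense, frameshift/in-frame indels, amplification) and *tmb* (adds
  silent and stop-loss; drops amplification), because burden counting
  includes synonymous variants while reporting does not.
- **EGFR subtyping.** Protein-level HGVS is parsed and mapped to the
  clinical vocabulary — 19del (in-frame deletion/delins within codons
  729–761), L858R, T790M, G719X (G719A/C/S), S768I, L861Q, 20ins (in-frame
  insertion/duplication within codons 762–823), other_uncommon, with
  sample-level `wildtype` / `multiple` labels.
- **TMB.** `TMB = n_variants / coding_region_Mb` after driver exclusion.
  TMB-High is `TMB ≥ cutoff` (10 mut/Mb on WES). The panel cutoff comes
  from quantile matching: with `p = P(TMB_WES < 10)` in a reference
  population, the panel cutoff is the empirical `p`-quantile (linear
  interpolation between order statistics) of the panel TMB distribution.
- **MSI.** Per locus, reads at repeat lengths with panel-of-normals
  frequency < 1% are "novel"; a locus is unstable when novel reads ≥ 20% of
  coverage. MSI score = unstable fraction over the 30 best-covered loci;
  MSI-H iff score ≥ 0.4.
- **TPS tiers.** negative (< 1%), intermediate positive ([1%, 50%)), strong
  positive (≥ 50%).
- **TIME densities.** Cells/mm² per cell type (CD8⁺ T, M1/M2 TAM,
  CD56^bright/dim NK) and compartment; the total compartment sums counts
  and areas before dividing. Group comparisons use Welch's t (two groups)
  or one-way ANOVA.
- **Survival.** Top-half ("median") density split, Kaplan–Meier
  product-limit curves, two-group log-rank, univariate Cox
  proportional-hazards (Efron ties) reporting HR with 95% CI.

## Worked example

```bash
python analysis/01_simulate_cohort.py       # writes results/cohort/
python analysis/03_tmb_harmonization.py
```

The harmonization step prints (seed 0, 500-sample default cohort, 254
EGFR-wildtype reference samples):

```
reference n=254: WES TMB-Low proportion p=0.713; harmonized panel cutoff = 15.2 mut/Mb
```

meaning 71.3% of wildtype reference samples are TMB-Low on WES at
10 mut/Mb, and the panel cutoff that classifies the same fraction of the
panel TMB distribution as TMB-Low is 15.2 mut/Mb. The remaining drivers
(`02_subtype_frequencies`, `04_msi_scoring`, `05_time_comparisons`,
`06_survival`) print subtype tables, MSI calls, density comparisons and
stratified PFS results, and write their tables under `results/`.

The same stages are available as a CLI:

```bash
nsclc-biomarkers simulate --n-samples 500 --seed 0 --out results/cohort
nsclc-biomarkers harmonize-tmb wes.tsv panel.tsv --wes-cutoff 10
nsclc-biomarkers report --cohort ... --variants ... --out results/report
```

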