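# Methods

This note documents the models and procedures implemented in
`nsclc_biomarkers`, the defaults and why they were chosen, and the known
limits of what the synthetic cohorts can demonstrate.

## Somatic variant filtering

Variants arrive annotated (gene, protein HGVS, consequence class, allele
fraction, population frequencies). The cascade keeps a call iff

1. allele fraction ≥ `min_af` (default 0.05, boundary inclusive);
2. max population frequency across databases ≤ `max_pop_freq` (default
   0.015; strictly greater is removed as likely germline/common — the
   maximum across databases is used, exposed in the profile);
3. consequence ∈ the profile's retained set.

Two profiles resolve an internal tension in clinical practice: reporting
retains stopgain/missense/frameshift/in-frame indels plus amplifications
(exempt from the AF rule, as gene-level events have no allele fraction),
while burden counting ("tmb") retains silent and stop-loss variants and
excludes amplifications (not SNVs/indels). Filtering is order-preserving
and idempotent by construction.

## EGFR subtyping

Protein HGVS is normalized (three-letter codes folded to one-letter) and
parsed with explicit grammars for substitutions, deletions/delins,
insertions/duplications and frameshifts. Categories use the canonical
transcript's residue→exon windows (exon 18: 688–728, exon 19: 729–761,
exon 20: 762–823, exon 21: 824–875):

- 19del: in-frame deletion or delins fully within codons 729–761;
- exact point categories L858R, T790M, S768I, L861Q; G719A/C/S → G719X;
- 20ins: in-frame insertion/duplication within codons 762–823;
- anything else (including amplification, exon-18 delins, out-of-window
  duplications) → other_uncommon.

Sample level: no EGFR alteration → wildtype; one distinct category → that
label; two or more distinct categories → multiple (so T790M co-occurring
with a sensitizing mutation is "multiple", while two different G719
substitutions remain G719X). Classification is a pure, order-insensitive
function of the variant list. Syntactically invalid HGVS raises; valid but
unrecognized forms fall to other_uncommon rather than erroring, because
cohort data always contains rare forms.

Frequency tables report count and percent (2 decimals) per label. For
published tables that count a patient in several overlapping rows while
reporting percentages of the patient total, an explicit denominator can be
supplied; otherwise counts partition the cohort.

## TMB and cutoff harmonization

`TMB = n / assay_Mb`, with `n` the number of retained coding SNVs/indels
not matching the driver list (exact gene+protein-change entries, plus
whole-gene entries; a canonical hotspot list ships as plain config).
Default footprints: 35 Mb (WES-like), 2.2 Mb (733-gene panel); both are
config, not measurements. TMB-High iff value ≥ cutoff, inclusive.

Harmonization transfers the WES cutoff (10 mut/Mb) to the panel by
matching the TMB-Low proportion on a reference population:
`p = P(TMB_WES < cutoff)` (strictly below, the complement of the inclusive
TMB-High rule), and the panel cutoff is the empirical `p`-quantile of the
panel reference values with linear interpolation between order statistics
at position `p·(n−1)` — the standard convention, chosen because it is
smooth, matches an independent sort-and-interpolate oracle exactly, and
guarantees the reproduced TMB-Low proportion lies within `1/n` of `p`.
Degenerate `p ∈ {0, 1}` returns the min/max with a warning flag rather
than failing.

## MSI scoring

Each locus carries a read-count histogram over repeat lengths plus a
panel-of-normals baseline. The locus-level rule had to be made concrete:
a repeat length is *novel* when its baseline frequency is below
`novel_support_min` (default 0.01), and the locus is unstable when novel
reads are at least `instability_fraction_min` (default 0.20, inclusive) of
coverage. Both thresholds are exposed. Per sample, the 30 best-covered
loci are evaluated (ties broken deterministically by locus id and logged;
fewer than 30 loci are used with a warning); MSI score = unstable
fraction; MSI-H iff score ≥ 0.4 (inclusive, so 12/30 is MSI-H).

## TPS and TIME

TPS tiers: negative < 1 ≤ intermediate < 50 ≤ strong. The interval
[49, 50) is assigned to intermediate so the tiers partition [0, 100];
this is forced by defining strong as ≥ 50. Densities are
count/area (cells/mm²); the *total* compartment sums counts and sums areas
before dividing (not the mean of densities), so it equals the density of
the pooled region. Group comparisons default to Welch's t for two groups
(robust to unequal variances; no selection rule between t variants is
imposed) and one-way ANOVA for more. p-values are reported raw; a
Benjamini–Hochberg helper is provided but never applied by default.

## Survival

Stratification uses the rank-based top-half rule: samples sorted by
descending density, the top ⌈n/2⌉ labeled high; boundary ties break by
sample id with a logged warning. This differs from thresholding at the
median value exactly when ties straddle the boundary, which is why the
rank form is specified. Kaplan–Meier, the two-group log-rank test and the
univariate Cox model are surfaced from lifelines/statsmodels (PHReg, Efron
tie handling by default with Breslow as an option); the test suite checks
them against independent brute-force oracles (hand product-limit,
hypergeometric sums, partial-likelihood grid search). Cox non-convergence
(e.g. a covariate that perfectly separates the event order) raises with
diagnostics rather than returning a divergent estimate. Times are months.

## Synthetic cohorts

The generator draws, per sample: an EGFR subtype from configured
frequencies; representative HGVS alterations for that subtype (chosen so
the subtyping module recovers the drawn label — the round-trip property);
log-normal TMB per subtype and assay; MSI status (Bernoulli) with
per-locus histograms; a TPS tier mixture with uniform within-tier values;
log-normal densities per cell type/compartment/EGFR group with Poisson
count noise; and exponential PFS with hazard
`λ = λ₀ · HR_egfr^[mutated] · HR_cd8^[CD8-low]` and independent uniform
censoring on [0, 60] months.

Defaults (in `data/default_cohort.yaml`) encode the study conditions the
pipeline targets: 51.3% EGFR prevalence with 19del/L858R at 39.52%/42.61%
of mutated samples; wildtype WES TMB log-normal(meanlog 1.846, sdlog 0.9),
i.e. 69.4% below 10 mut/Mb, and a panel distribution whose matching
quantile sits near 14.5 mut/Mb; MSI-H prevalence 0.8%; common sensitizing
subtypes (19del, L858R, T790M, 20ins) placed below wildtype/uncommon
subtypes in TMB; a CD8 tumor-density deficit in mutated samples (meanlog
5.3 → 4.7, sdlog 0.5); baseline hazard ln2/27 per month (median PFS 27
months) with HRs 1.6 (EGFR mutated) and 2.0 (CD8-low). Per-subtype TMB
spreads and density parameters for the other populations are illustrative
choices of plausible magnitude, not estimates.

MSI-H samples perturb 70% of loci by moving 40% of reads to repeat
lengths 4–5 units below the modal length (deletion-type instability);
MSS samples add only ~0.4% stutter mass at adjacent novel lengths. Under
the default caller thresholds this yields an expected score near 0.7 for
MSI-H and near 0 for MSS, so both classifications are recovered with high
probability — the Monte-Carlo calibration in the acceptance suite
quantifies this. At cohort scale, histograms are generated for every MSI-H
sample but only a capped number of MSS samples (default 200): MSS
histograms are exchangeable and the cap keeps 5000-sample generation
cheap; `generate_msi_profiles` remains callable for any sample.

Determinism: one global seed; each sub-generator derives a child generator
by a fixed offset, so regeneration with the same config+seed is
byte-identical in all serialized outputs (fixed float formats, sorted
orders).

**What passing tests do and do not show.** The synthetic cohorts reproduce
marginal and simple conditional structure (frequencies, per-subtype
distributions, one density shift, proportional hazards with exponential
baselines). They do not emulate: assay noise in variant calling, indel
normalization artifacts, correlated biomarkers beyond the CD8–EGFR and
CD8–survival links, non-proportional hazards, informative censoring, or
real microsatellite stutter structure. Green tests certify the pipeline's
operations and their contracts, not clinical performance on real data.

## Problem sizes

The test and acceptance workloads were sized to exercise the asymptotics
that matter while staying quick: exhaustive quantile-oracle checks over
all panel multisets of length ≤ 12 from a 4-value alphabet plus 1000
random float lists; round-trip recovery at n = 5000; 200-seed MSI
Monte-Carlo; Cox recovery with 200 replicates of n = 300 and null CI
coverage with 500 replicates of n = 100; exhaustive KM checks on all
no-censoring multisets of length ≤ 8 over a 3-point time grid.

## Known limitations

- Nucleotide-level (c.) HGVS is out of scope; classification is purely
  protein-level, so splice-region alterations land in other_uncommon.
- The MSI locus rule is a deliberately simple novel-length criterion, not
  a paired tumor-normal site model (MANTIS/MSIsensor class).
- TMB carries no confidence interval; panel-size defaults are nominal.
- The pipeline consumes annotated calls and cell counts; it does not call
  variants or segment images.
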