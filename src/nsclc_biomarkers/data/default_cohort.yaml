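# Default synthetic-cohort parameters.
#
# Calibrated to the cohort structure the pipeline is designed for:
# ~51.3% EGFR mutation prevalence with 19del/L858R at 39.52%/42.61% of
# mutated samples; wildtype WES TMB log-normal with 69.4% of mass below
# 10 mut/Mb and a panel distribution whose matching quantile sits near
# 14.5 mut/Mb; MSI-H prevalence under 1%; common sensitizing subtypes
# carry lower TMB than wildtype/uncommon subtypes.

n_samples: 500
seed: 0

subtype_probs:
  wildtype: 0.487
  19del: 0.2027376
  L858R: 0.2185893
  T790M: 0.0128250
  G719X: 0.0179550
  S768I: 0.0153900
  L861Q: 0.0076950
  20ins: 0.0102600
  other_uncommon: 0.0147231
  multiple: 0.0128250

# Per-subtype log-normal TMB parameters [meanlog, sdlog] per assay,
# in mutations/Mb.
tmb_params:
  wildtype:       {wes: [1.846, 0.9], panel: [2.218, 0.9]}
  19del:          {wes: [1.32, 0.9],  panel: [1.692, 0.9]}
  L858R:          {wes: [1.42, 0.9],  panel: [1.792, 0.9]}
  T790M:          {wes: [1.38, 0.9],  panel: [1.752, 0.9]}
  G719X:          {wes: [1.70, 0.9],  panel: [2.072, 0.9]}
  S768I:          {wes: [1.83, 0.9],  panel: [2.202, 0.9]}
  L861Q:          {wes: [1.68, 0.9],  panel: [2.052, 0.9]}
  20ins:          {wes: [1.15, 0.9],  panel: [1.522, 0.9]}
  other_uncommon: {wes: [1.80, 0.9],  panel: [2.172, 0.9]}
  multiple:       {wes: [1.55, 0.9],  panel: [1.922, 0.9]}

msi_h_prob: 0.008
msi_n_loci: 100
mss_profile_cap: 200

# Tier weights [negative, intermediate_positive, strong_positive]; TPS is
# drawn uniformly inside the selected tier's interval.
tps_mixture:
  wildtype:       [0.42, 0.38, 0.20]
  19del:          [0.60, 0.32, 0.08]
  L858R:          [0.58, 0.33, 0.09]
  T790M:          [0.55, 0.35, 0.10]
  G719X:          [0.45, 0.37, 0.18]
  S768I:          [0.44, 0.38, 0.18]
  L861Q:          [0.50, 0.36, 0.14]
  20ins:          [0.62, 0.30, 0.08]
  other_uncommon: [0.45, 0.37, 0.18]
  multiple:       [0.55, 0.33, 0.12]

# Log-normal density parameters [meanlog, sdlog] of cells/mm2 per cell type,
# compartment (tumor/stroma) and EGFR group (wildtype/mutated). The CD8
# tumor-compartment shift encodes lower CD8 infiltration in mutated tumors.
density_params:
  CD8_T:
    tumor:  {wildtype: [5.30, 0.5], mutated: [4.70, 0.5]}
    stroma: {wildtype: [5.70, 0.5], mutated: [5.60, 0.5]}
  M1_TAM:
    tumor:  {wildtype: [4.00, 0.6], mutated: [3.90, 0.6]}
    stroma: {wildtype: [4.50, 0.6], mutated: [4.50, 0.6]}
  M2_TAM:
    tumor:  {wildtype: [4.80, 0.6], mutated: [4.90, 0.6]}
    stroma: {wildtype: [5.20, 0.6], mutated: [5.30, 0.6]}
  CD56bright_NK:
    tumor:  {wildtype: [2.50, 0.7], mutated: [2.40, 0.7]}
    stroma: {wildtype: [3.00, 0.7], mutated: [3.00, 0.7]}
  CD56dim_NK:
    tumor:  {wildtype: [3.20, 0.7], mutated: [3.10, 0.7]}
    stroma: {wildtype: [3.60, 0.7], mutated: [3.60, 0.7]}

# Exponential PFS model: baseline hazard per month (median ~27 months) with
# multiplicative hazard ratios per stratum flag; independent uniform
# censoring on [0, censoring_max_months].
survival_params:
  baseline_hazard: 0.02567
  hazard_ratios:
    egfr_mutated: 1.6
    cd8_tumor_low: 2.0
  censoring_max_months: 60.0
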