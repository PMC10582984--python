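# Default synthetic-cohort configuration.
#
# Cohort sizes, phenotype prevalences, HLA stratum sizes and effect sizes
# mirror the published Swedish/Norwegian female SLE cohort that the B cell
# PRS analysis was developed on (1248 patients, 400 blood-donor controls).
# Effects are expressed on the scale the analysis estimates them: odds
# ratios for the high-vs-low (fourth quartile vs quartiles 1-3) PRS
# indicator or for dsDNA status, and a hazard ratio for time to lupus
# nephritis onset.

n_cases: 1248
n_controls: 400

# Patients per HLA-DRB1*03:01 / *15:01 tag-SNP stratum (normalised to
# proportions at generation time).
hla_stratum_weights:
  neg_neg: 354
  single_pos: 656
  double_pos: 143

# Marginal outcome prevalences among patients ("ever positive" fractions).
prevalences:
  malar_rash: 0.567
  discoid_rash: 0.220
  photosensitivity: 0.692
  oral_ulcer: 0.280
  arthritis: 0.774
  serositis: 0.375
  renal: 0.297
  neurological: 0.093
  haematological: 0.642
  immunological: 0.695
  ana: 0.983
  dsdna: 0.626
  sm: 0.115
  low_complement: 0.554

# True generating effects. "stratum" restricts an effect to one HLA group;
# un-stratified entries apply cohort-wide. Exposures: bcell_high /
# activation_high are fourth-quartile PRS indicators; dsdna is antibody
# status.
effects:
  - {outcome: sle, exposure: bcell_high, effect_type: OR, value: 1.64}
  - {outcome: sle, exposure: activation_high, effect_type: OR, value: 1.58}
  - {outcome: dsdna, exposure: bcell_high, effect_type: OR, value: 1.47}
  - {outcome: immunological, exposure: bcell_high, effect_type: OR, value: 1.44}
  - {outcome: renal, exposure: activation_high, effect_type: OR, value: 1.32}
  - {outcome: dsdna, exposure: bcell_high, stratum: neg_neg, effect_type: OR, value: 0.99}
  - {outcome: dsdna, exposure: bcell_high, stratum: single_pos, effect_type: OR, value: 1.64}
  - {outcome: dsdna, exposure: bcell_high, stratum: double_pos, effect_type: OR, value: 4.47}
  - {outcome: immunological, exposure: bcell_high, stratum: single_pos, effect_type: OR, value: 1.54}
  - {outcome: low_complement, exposure: bcell_high, stratum: double_pos, effect_type: OR, value: 3.92}
  - {outcome: ln, exposure: dsdna, effect_type: OR, value: 2.80}
  - {outcome: time_to_ln, exposure: dsdna, effect_type: HR, value: 2.89}

# Nuisance-covariate coefficients used when generating outcomes: binary
# outcomes get duration_beta * (duration - mean duration) on the logit
# scale; LN onset hazard gets age_beta * (age_at_onset - mean age).
duration_beta: 0.02
age_beta: -0.01

# Disease duration (years since diagnosis at follow-up) and age at onset,
# log-normal on the natural scale; medians anchor the distributions.
duration_lognormal: {median: 18.0, sigma: 0.6}
age_at_onset_lognormal: {median: 35.0, sigma: 0.45, min: 3.0, max: 82.0}

# Exponential time-to-LN baseline hazard (events/year, dsDNA-negative
# reference) and independent exponential censoring.
survival:
  baseline_rate: 0.012
  censoring_rate: 0.04
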