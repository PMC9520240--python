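# Default model parameters: published point estimates with the
# distributions used in the probabilistic sensitivity analysis.
# Beta rows carry the published alpha/beta shape terms where available;
# otherwise shapes are derived by method of moments from mean/SE.
# Lognormal rows are sampled by natural-scale moment matching of mean/SE
# (both the printed SEs and CIs are stored; the SE is the sampled quantity).
# Costs are 2021 euros.
parameters:
  # intervention effects (hazard ratios on T2D incidence)
  hr_lifestyle: {family: lognormal, mean: 0.74, se: 0.17, ci: [0.53, 1.03]}
  hr_combined: {family: lognormal, mean: 0.51, se: 0.10, ci: [0.37, 0.69]}
  # mortality hazard ratios by health state
  hr_mort_t2d_female: {family: lognormal, mean: 2.47, se: 0.12, ci: [2.23, 2.72]}
  hr_mort_t2d_male: {family: lognormal, mean: 1.93, se: 0.07, ci: [1.79, 2.07]}
  hr_mort_complications: {family: lognormal, mean: 2.36, se: 0.34, ci: [1.70, 3.29]}
  # annual and one-off costs (EUR)
  cost_productivity_t2d: {family: gamma, mean: 7632, se: 974, ci: [5724, 9540]}
  cost_complications: {family: gamma, mean: 4401, se: 561, ci: [3301, 5501]}
  cost_t2d_secondary: {family: gamma, mean: 3315, se: 423, ci: [2486, 4144]}
  cost_medical_therapy: {family: fixed, mean: 1965}
  cost_lifestyle: {family: gamma, mean: 650, se: 83, ci: [488, 813]}
  cost_prs_test: {family: fixed, mean: 50}
  cost_primary_male: {family: gamma, mean: 562, se: 9.53}
  cost_primary_female: {family: gamma, mean: 542, se: 9.82}
  cost_t2d_medication: {family: gamma, mean: 584, se: 74, ci: [438, 730]}
  # EQ-5D-3L utilities
  utility_female_30_44: {family: beta, mean: 0.906, se: 0.003, alpha: 8573, beta: 889}
  utility_female_45_54: {family: beta, mean: 0.865, se: 0.005, alpha: 4040, beta: 631}
  utility_female_55_64: {family: beta, mean: 0.810, se: 0.006, alpha: 3463, beta: 812}
  utility_female_65plus: {family: beta, mean: 0.770, se: 0.008, alpha: 2130, beta: 636}
  utility_male_30_44: {family: beta, mean: 0.917, se: 0.003, alpha: 7755, beta: 702}
  utility_male_45_54: {family: beta, mean: 0.876, se: 0.005, alpha: 3806, beta: 539}
  utility_male_55_64: {family: beta, mean: 0.821, se: 0.006, alpha: 3351, beta: 731}
  utility_male_65plus: {family: beta, mean: 0.781, se: 0.008, alpha: 2087, beta: 585}
  disutility_t2d: {family: beta, mean: 0.041, se: 0.012, alpha: 11.15, beta: 260.9}
  disutility_complications: {family: beta, mean: 0.119, se: 0.0209, ci: [0.078, 0.160], alpha: 55.45, beta: 410.50}
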