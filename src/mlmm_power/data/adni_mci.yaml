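# Default population parameters for power analysis in early Alzheimer's
# disease: annual rates of change and covariance structure of transformed
# MMSE, CDR-SB and ADAS-11 scores fitted to ADNI mild-cognitive-impairment
# participants (random-intercept multivariate linear mixed model; scores
# transformed so higher = worse and scaled by baseline SD).
labels: [MMSE, CDR-SB, ADAS-11]
beta2: [0.079, 0.061, 0.055]
sigma_eps:
  - [0.56, 0.07, 0.09]
  - [0.07, 0.57, 0.06]
  - [0.09, 0.06, 0.44]
sigma_b:
  - [0.58, 0.30, 0.48]
  - [0.30, 0.71, 0.37]
  - [0.48, 0.37, 0.77]
effect:
  mode: fraction_of_rate
  reduction_fraction: 0.25
design:
  duration_years: 2
  visit_interval_years: 0.5
  allocation: 0.5
  alpha: 0.05
  target_power: 0.80
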