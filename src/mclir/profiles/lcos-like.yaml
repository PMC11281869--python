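# Illustrative natural-history profile. Stage-specific screening
# sensitivities are the published values for the eponymous model;
# ALL other parameters are illustrative defaults, not a calibrated
# replica of that model.
schema_version: 1
profile_name: lcos-like
calibration_status: illustrative
long_sojourn_tail: false
onset_hazard:
  family: weibull
  shape: 5.0
  scale: 160.0
  beta_pack_years: 0.018
  beta_current_smoker: 0.2
  sex_multiplier_female: 0.9
sojourn_dist:
  family: mixture
  components:
  - family: exponential
    mean: 1.2
    weight: 0.55
  - family: weibull
    shape: 1.8
    scale: 3.2
    weight: 0.45
stage_dwell:
  fractions:
  - 0.35
  - 0.15
  - 0.15
  - 0.35
  mode: fixed
  progression_span: 3.2
sensitivity:
  by_stage:
  - 0.521
  - 0.618
  - 0.922
  - 0.926
survival:
  cure_by_stage:
  - 0.55
  - 0.4
  - 0.22
  - 0.04
  death_time:
    family: exponential
    mean_by_stage:
    - 5.0
    - 4.0
    - 2.5
    - 1.2
screen_detection_survival:
  mode: stage_shift_only
modifiers:
  female:
    sojourn_scale: 1.25
    sensitivity_scale: 1.03
    cure_scale: 1.08
  smoking: {}
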