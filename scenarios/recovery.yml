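adherence_params:
  discontinuation_coefs: {}
  discontinuation_hazard:
    aromatase_inhibitor: 0.0
    tamoxifen: 0.0
  switch_prob: 0.0
admin_end: '2015-12-31'
ai_drug_split:
  anastrozole: 0.35
  exemestane: 0.1
  letrozole: 0.55
comorbidity_correlation: 0.0
comorbidity_onset_rate: 0.0015
dispensation_supply_days:
  30: 0.15
  90: 0.55
  100: 0.3
drug_initiation_rate: 0.002
effect_modifier_coefs: {}
emigration_rate: 0.0
enrollment_end: '2010-12-31'
enrollment_start: '2009-08-01'
hazard_model_coefs:
  age_c: 0.075
  anticoagulants: 0.25
  antidepressants: 0.35
  cardiovascular_disease: 0.45
  cerebrovascular_disease: 0.5
  chemotherapy: 0.25
  copd: 0.5
  diabetes: 0.35
  employment:not_employed: 0.25
  grade:3: 0.45
  intercept: -7.5
  n_class:N1plus: 0.35
  opioids: 0.55
  stage:2: 0.45
  stage:3: 1.1
n_patients: 20000
seed: 0
treated_share: 0.6405552010210593
treatment_model_coefs:
  age: 0.02
  antidepressants: 0.4
  cardiovascular_disease: 0.5
  chemotherapy: 1.5
  copd: 0.5
  diabetes: 0.4
  opioids: 0.6
  stage:2: 0.8
  stage:3: 1.5
true_treatment_log_or: -0.0943
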