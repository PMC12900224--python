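# Default 1-year graft survival Cox model: donor warm-ischemia exposure as a
# restricted cubic spline plus donor and recipient confounders available in
# the registry schema.  Right-skewed covariates not splined are
# log2-transformed (effects per doubling).
name: graft_survival_1y
outcome_type: time-to-event
duration_col: graft_time_days
event_col: graft_event
horizon_days: 365
curve_terms: [ttd_min]
terms:
  - {name: ttd_min, kind: rcs}
  - {name: donor_age, kind: linear, scale: 10}
  - {name: donor_bmi, kind: linear, scale: 5}
  - {name: donor_sex, kind: categorical, reference: F}
  - {name: hypertension, kind: linear}
  - {name: cause_of_death, kind: categorical, reference: cerebrovascular}
  - {name: peak_alt, kind: log2}
  - {name: machine_perfusion, kind: categorical, reference: none}
  - {name: cold_ischemic_hours, kind: linear}
  - {name: recipient_age, kind: linear, scale: 10}
  - {name: recipient_bmi, kind: linear, scale: 5}
  - {name: recipient_sex, kind: categorical, reference: F}
  - {name: meld, kind: linear, scale: 10}
  - {name: dialysis, kind: linear}
  - {name: recipient_diabetes, kind: linear}
  - {name: status1a, kind: linear}
  - {name: diagnosis, kind: categorical, reference: ald}
  - {name: medical_condition, kind: categorical, reference: home}
  - {name: ethnicity, kind: categorical, reference: white}
  - {name: waitlist_days, kind: log2}
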