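# Default liver-utilization logistic model on the donor (utilization)
# cohort: TTD as a restricted cubic spline plus donor factors known to drive
# acceptance decisions.  Right-skewed labs are log2-transformed.
name: utilization
outcome_type: binary
outcome: utilized
curve_terms: [ttd_min]
terms:
  - {name: ttd_min, kind: rcs}
  - {name: asystolic_min, kind: rcs}
  - {name: blood_group, kind: categorical, reference: A}
  - {name: donor_age, kind: linear, scale: 10}
  - {name: donor_bmi, kind: linear, scale: 5}
  - {name: donor_sex, kind: categorical, reference: F}
  - {name: hypertension, kind: linear}
  - {name: diabetes, kind: linear}
  - {name: cause_of_death, kind: categorical, reference: cerebrovascular}
  - {name: peak_alt, kind: log2}
  - {name: peak_bilirubin, kind: log2}
  - {name: peak_albumin, kind: linear}
  - {name: peak_sodium, kind: linear}
  - {name: donation_year, kind: linear}
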