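# Demo synthetic-database configuration: two rare intravitreal drugs
# against a large background, one planted drug-event association.
n_reports: 50000
seed: 42
period: [2010-01-01, 2016-12-31]
drugs:
  - name: ranibizumab
    marginal_prob: 0.004
    route_dist: {intravitreal: 0.85, unreported: 0.15}
    elderly_multiplier: 3.0
  - name: aflibercept
    marginal_prob: 0.002
    route_dist: {intravitreal: 0.85, unreported: 0.15}
    elderly_multiplier: 3.0
events:
  - pt_name: Parkinson's disease
    baseline_prob: 0.002
    age_multiplier_per_decade: 1.5
  - pt_name: Parkinsonism
    baseline_prob: 0.001
    age_multiplier_per_decade: 1.5
  - pt_name: Dementia
    baseline_prob: 0.003
    age_multiplier_per_decade: 1.6
  - pt_name: Dementia Alzheimer's type
    baseline_prob: 0.0015
    age_multiplier_per_decade: 1.6
  - pt_name: Tremor
    baseline_prob: 0.004
planted_associations:
  - {drug_name: ranibizumab, pt_name: "Parkinson's disease", rrr: 3.0}
age:
  prop_ge65: 0.35
sex_ratio: 0.48
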