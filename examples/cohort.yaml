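# Example spec for `sigselect simulate`
n_samples: 200
n_signatures: 5
signature_concentration: 0.5
cancer_type: SYNTH
burden_mean: 200
burden_dispersion: 1.0   # null -> fixed burden
exposure_alpha: 0.5
drivers_per_sample: 1
drivers:
  - {label: "KRAS:G12C", channel: "C[C>A]A", gene: KRAS, relative_risk: 2.0}
  - {label: "KRAS:G12D", channel: "A[C>T]G", gene: KRAS, relative_risk: 1.0}
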