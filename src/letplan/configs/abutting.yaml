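archetype: abutting
objective:
  prescription: 54.0
  d95_floor: 51.0
  n_fractions: 30
  target_under_weight: 300.0
  target_over_weight: 120.0
  oar_weights:
    brainstem: 300.0
    spinal_cord: 300.0
  phi_t: 10.0
  phi_o: 10.0
scenarios:
  setup_mm: 2.25
  range_fraction: 0.035
biology:
  alpha_beta:
    ctv: 10.0
    brainstem: 2.0
    spinal_cord: 2.0
  n_fractions: 30
  c: 0.04
spots:
  lateral_spacing: 5.0
  layer_step: 5.0
solver:
  maxiter: 400
  seed: 0
evaluation:
  d95_reference: 54.0
  dose_threshold: 1.0
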