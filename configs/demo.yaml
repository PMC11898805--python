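# Demo pipeline: small synthetic study, full 3x4 benchmark grid.
seed: 42
synthetic:
  n_samples: 120
  fumigated_fraction: 0.5
  noise_sd: 0.02
  signature_depth: 0.1
selection:
  width: 20
  step: 10
  irf_iterations: 120
  irf_keep: 3
  vcpa_runs: 8
  vcpa_bms: 80
  final_pool: 8
  folds: 5
training:
  epochs: 20
  patience: 0
  batch_size: 16
evaluation:
  target: label
  test_fraction: 0.3
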