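# Default benchmark configuration, version-pinned so Monte Carlo percentile
# bands are reproducible. Resonances and the unidirectional coupling chain are
# the constraints the benchmarks must satisfy; pole radii, coupling values and
# per-realization data length are free choices documented in docs/methods.md.
fs: 120.0

three_node:
  resonances_hz: [40.0, 10.0, 50.0]
  pole_radius: 0.9
  # source -> target couplings; lag chosen so the model is a genuine VAR(3)
  couplings:
    - {source: 1, target: 2, lag: 2, value: 0.35}
    - {source: 2, target: 3, lag: 3, value: 0.35}
  innovation_variances: [1.0, 1.0, 1.0]
  order: 3

two_node:
  transmitter_hz: 50.0
  receiver_hz: 10.0          # studied at 10 / 30 / 50 Hz
  pole_radius: 0.9
  couplings:
    - {source: 1, target: 2, lag: 1, value: 0.35}
  innovation_variances: [1.0, 1.0]
  order: 2

study:
  n_samples: 500
  n_realizations: 100
  master_seed: 0
  burn_in: 1000
  n_freq: 513
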