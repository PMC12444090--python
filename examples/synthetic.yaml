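# Synthetic linear-Gaussian study: one signal feature, noise sd 1,
# hence a known limit test R² of 0.5 for any consistent regression model.
pool:
  synthetic:
    n_samples: 600
    weights: [1.0]
    noise_sd: 1.0
    seed: 42
adapter:
  name: ols
study:
  split_fraction: 0.7
  ladder: [20, 40, 60, 80, 100]
  instances: 2
  base_reps: 50
  tolerance: 0.01
  max_reps_cap: 50000
  seed: 7
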