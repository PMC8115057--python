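# Static choice behavior over safety priors and CAB interaction strengths
# (learning disabled).
experiment: sweep
seed: 1
protocol:
  danger_grid: [1.0, 0.9, 0.75, 0.5, 0.25, 0.1, 0.0]
  cab_grid: [0.1, 0.5, 0.9]
  n_sweep_trials: 100
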