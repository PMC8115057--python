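# Exposure without prior cognitive restructuring (strong danger belief),
# with strong cognition-affect-behavior interactions.
experiment: exposure
seed: 1
params:
  danger: 0.9
  cab_i: 0.9
protocol:
  exposure_lengths: [0, 10, 25, 50, 75, 100, 150, 200]
  n_probe_reps: 50
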