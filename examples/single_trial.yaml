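# One free-choice trial before cognitive restructuring: a patient with a
# fully precise danger belief meets an objectively safe spider.
experiment: single_trial
seed: 1
params:
  danger: 1.0
  cab_i: 0.9
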