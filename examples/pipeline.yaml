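# End-to-end example: simulate a small experiment with attraction and both
# systematic report biases, then run the folded-error and build-up analyses.
#   serialdep report --config examples/pipeline.yaml --out out --seed 1
seed: 1
simulate:
  n_subjects: 5
  n_trials: 200
  sigma: 0.006
  n_steps: 50
  inhom_amplitude: 0.2
  inhom_frequency: 4
  rotation_bias: 1.4      # degrees
  dog:
    a: 0.09
    w: 0.007
analyze:
  reference: target
  folded: true
  guess_threshold_deg: 90
  max_distance_deg: 90
  n_boot: 1000
buildup:
  enabled: true
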