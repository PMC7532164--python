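# Demo pipeline configuration for `trajmine run`.
# Runs end-to-end on one CPU in well under a minute:
#   trajmine run --config examples/run_config.yaml --seed 1 --out out/
simulate:
  n_patients: 8000
  code_universe:
    A09: 0.004
    E11: 0.004
    I10: 0.005
    I50: 0.003
    N18: 0.003
    Z51: 0.002
  rules:
    - source: I10
      target: I50
      hazard_multiplier: 25.0
  death_hazard:
    0: 0.001
    70: 0.02
thresholds:
  n_controls: 100
min_followers: 10
max_length: 6
sex: all
min_patients: 5
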