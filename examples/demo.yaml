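# Desk-scale demonstration cohort: 4 men + 2 women, REM + slow-wave sleep.
# Run with:  somnonet run --config examples/demo.yaml --out results_demo --seed 42
seed: 42
stages: ["3", "4", "REM"]
order: 3
n_freqs: 256
n_surrogates: 10
density: 0.2
cohort:
  n_men: 4
  n_women: 2
  epochs_per_stage: 5
  artifact_fraction: 0.1
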