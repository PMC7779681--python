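# example pipeline configuration for `koa run --config pipeline.example.yaml`
out_dir: out
seed: 7
simulate:
  n_patients: 518
  n_visits: 5
  missing_rate: 0.05
preprocess:
  k_donors: 5
logistic:
  alpha: 0.5
markov:
  smoothing: 0.0
lstm:
  epochs: 200
  lr: 0.5
  hidden_size: 32
fci:
  alpha: 0.01
  max_depth: 3
evaluate:
  folds: 10
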