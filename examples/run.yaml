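# Small end-to-end pipeline configuration for `qeyed run --config examples/run.yaml`.
# Simulates a 6-participant cohort, cleans it (scenario C vs raw A), trains a
# CNN-GRU and the SVM baseline, and writes Table-style report files.
sim:
  n_shots: 4
n_participants: 6
scenarios: [A, C]
models:
  - family: cnn_gru
    params: {pool: 8}
  - family: svm
train:
  epochs: 15
  batch_size: 8
  validation_fraction: 0.0
folds: 3
tolerance: 0.1
master_seed: 7
output_dir: scratch/demo_run
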