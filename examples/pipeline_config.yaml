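# Fully-populated default pipeline configuration.
# Every key shown here is optional; omitted keys fall back to these values.

filter:
  notch_hz: 50.0
  band: [0.15, 45.0]
epoch_length_s: 1.0

feature_mode: entropy_fusion    # entropy_fusion | entropy_subset | ar
measures: [PE, AE, SE, FE]      # used by entropy_subset mode
entropy:
  m: 2
  r_factor: 0.2
  n_grad: 2
ar:
  order: 10

normalization:
  new_min: -1.0
  new_max: 1.0
  per_subject: true

classifiers: [rbf_svm, feedforward_net, random_forest, nearest_neighbor]
classifier_params:
  c: 0.5          # 2^-1
  g: 0.03125      # 2^-5
  hidden_units: 20
  n_trees: 500
  mtry: 22
  k_neighbors: 5
  n_restarts: 1

cv:
  scheme: leave_one_out   # leave_one_out | holdout
  unit: epoch             # epoch | subject
  holdout_fraction: 0.5

electrodes: null          # list of names, a region key (A-D), or null for all
regions:
  A: [TP7, T5, P3, CP3]
  B: [FCz]
  C: [T4]
  D: [O1, Oz, T6]
select_channels: false    # also compute the accuracy-weight electrode ranking

seed: 0
output_dir: entrofuse_out
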