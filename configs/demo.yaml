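# Small demo study: one-command pipeline configuration.
synth:
  n_participants: 60
  seed: 11
  nonlinear_effect_flag: true
pooling:
  include_response_day: true
stats:
  m_imputations: 5
ml:
  outer_folds: 5
  inner_folds: 2
  classifiers: [RF, LR]
  grids:
    RF: {n_estimators: [100], max_depth: [null, 10]}
    LR: {C: [0.1, 1.0]}
    DT: {max_depth: [null, 3]}
  permutation_repeats: 3
  with_demographics: false
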