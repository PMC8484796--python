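# Demo pipeline: fully simulated two-cohort study, 200 samples total.
seed: 42
out_dir: demo_out
simulation:
  n_samples: 100
  n_cohorts: 2
k_range: [2, 4]
reps: 100
subsample: 0.8
n_trees: 200
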