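# Cohort configuration for `waterreach run-all`.
seed: 5
out_dir: example_run
n_trials: 40
cohort:
  WT: [wt1, wt2]
  HD: [hd1, hd2]
days: [8, 45]
day_params:
  HD:
    45:
      success: 0.35
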