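# Desk-scale old/new-task experiment: protocol epoch windows and montage,
# reduced trial counts and iteration numbers so the run finishes in minutes.
experiment: 1
n_subjects: 4
n_iterations: 10
run_tg: true
n_permutations: 100
permutation_iterations: 3
n_bootstrap: 2000
rois: [all, frontocentral]
seed: 1
out_dir: enscode_exp1
sim:
  n_trials_so: 96
  n_trials_vo: 48
  epoch_window: [-0.2, 0.8]
  noise_sd: 1.0
  ensemble_weight: 0.5
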