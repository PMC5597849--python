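# Demo pipeline configuration: completes on one CPU in a few minutes.
outdir: demo_out
seed: 7
simulate: true
synth:
  n_case: 40
  n_control: 40
  n_species: 50
  genes_per_species: 20
  n_diff_species: 2
  effect_log2fc: 2.0
  depth_mean: 200000.0
k_axes: 2
q_threshold: 0.05
rho_min: 0.7
min_size: 5
rho_cut: 0.4
min_mean_abund: 1.0e-5
compare_min_mean_abund: 5.0e-4
rarefaction_depth: 50000
rarefaction_draws: 30
n_perm: 999
n_trees: 200
n_boot: 500
cv_folds: 5
cv_repeats: 3
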