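# Full-pipeline configuration for `neuroparti run`.
# With no input paths the pipeline simulates a synthetic study first.
output_dir: neuroparti_run
seed: 7
k: 3
n_shuffles: 1000        # full-scale: 10000
n_boot: 1000            # full-scale: 10000
n_surrogates: 1000      # full-scale: 10000
n_bins: 10
q_enrich: 0.1
q_posthoc: 0.05
penalty: 0.1            # hinge penalty for position fitting / bootstrap
t_ratio_penalty: 5.0    # harder enclosure for the significance test
distance_space: original
run_loo: true
simulate:
  n: 900
  d: 19
  noise_frac: 0.02
  dirichlet_alpha: 1.0
  shift_fraction: 0.5
  n_clinical: 120
  grid_shape: [8, 8, 8]
# To run on real data instead, delete `simulate` and set:
# compositions_path: compositions.tsv
# confounds_path: confounds.tsv
# features_path: features.tsv
# maps_path: component_maps.nii.gz
# groups:
#   clinical: clinical_compositions.tsv
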