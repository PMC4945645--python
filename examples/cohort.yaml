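# Desk-scale synthetic cohort: two groups differing only in band-3 coupling.
# Run:  muxbrain run-all --config examples/cohort.yaml --seed 7
output_dir: runs/demo
synthetic:
  n_subjects_per_group: 5
  n_rois: 20
  n_timepoints: 180
  background_strength: 0.8
  group_effects:
    1: [[3, [0, 1, 2, 3, 4, 5, 6, 7, 8, 9], 1.0]]
band_scheme: [0.01, 0.25, 0.02]
n_surrogates: 50
z_threshold: 3.0
D: 1.0
top_k: 5
rf_params: {n_estimators: 150, max_leaf_nodes: 5, max_features: 2}
seed: 7
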