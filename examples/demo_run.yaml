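# Demo pipeline configuration: a 20-subject synthetic cohort with planted
# local-coherence, hub and edge-behaviour effects; completes in well under a
# minute on one CPU.  Run with:  limbiccog run --config examples/demo_run.yaml
out_dir: scratch/demo_run
n_perm: 200
cpm_n_perm: 99
cpm_p_threshold: 0.01
alpha_reliability: 0.88
score_name: rbans_t
visit: week12
seed: 7
design:
  n_bd: 12
  n_hc: 8
  grid_shape: [8, 8, 8]
  n_timepoints: 80
  n_regions: 8
  reho_effect_regions: [1]
  coherence_boost: 0.7
  dc_hub_regions: [2]
  hub_strength: 0.8
  behavior_edges: [[3, 4, -1.0], [5, 6, -1.0]]
  edge_coupling: 0.5
  edge_coupling_sd: 0.3
  seed: 7
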