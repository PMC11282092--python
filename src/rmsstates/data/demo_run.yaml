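# Bundled demo configuration: a small 8-sample cohort (4 pre- / 4 on-treatment)
# with the four dominant states, full pipeline enabled.
outdir: rms_demo
seed: 0
simulate:
  n_samples: 8
  cells_per_sample: 250
  n_genes: 1500
  marker_log_fold_change: 1.0
  treatment_status: [pre, pre, pre, pre, "on", "on", "on", "on"]
  treatment_shift:
    progenitor: 2.0
n_pcs: 15
n_neighbors: 20
resolution: 0.3
cluster_method: louvain
n_hvg: 1500
stages:
  preprocess: true
  consensus: true
  score: true
  states: true
  devmap: true
  shift_test: true
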