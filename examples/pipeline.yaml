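# Demonstration-scale pipeline configuration.
# Every stage parameter is surfaced here; stochastic stages refuse to run
# without a seed (pass --seed on the CLI or set it here).
seed: 7
simulate:
  n_genes: 150
  n_cells_per_sample: 400
  n_samples_per_group: 2
  grid_side: 16
qc:
  min_counts: 500        # matched to the simulated depth; real-data default 1000
  max_mito: 0.15
  min_cells_per_sample: 100
markers:
  min_fraction: 0.1
  min_log2fc: 0.25
mia:
  top_n: 100
  max_q: 0.05
spatial:
  k: 6
  n_perms: 1000
  radial_target: interface
  n_bins: 25
coloc:
  genes_a: auto          # flagship marker of the first interface partner
  genes_b: auto          # marker pair of the second partner
  k: 6
  trim_q: 0.99
  top_frac: 0.10
cohort:
  within: null
stages:
  simulate: true
  qc: true
  markers: true
  mia: true
  spatial: true
  coloc: true
  cohort: true
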