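# Worked-example study: 1000 genes, 12% cyclers per condition, and a
# 300-node low-rewiring small-world network with assortative placement.
simulation:
  n_genes: 1000
  frac_cycling_18: 0.12
  frac_cycling_25: 0.12
  frac_shared: 0.6
  amplitude_range: [1.0, 2.0]
  noise_sd: 0.4
  baseline_log_tpm_mean: 6.0
network:
  n_nodes: 300
  graph_params: {k: 6, p: 0.02}
  per_edge_phase_step: 2.0
  placement_noise_sd: 0.5
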