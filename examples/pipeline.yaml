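# Demo pipeline config: pure simulation mode, every stage enabled.
# Run:  coopdeg run --config examples/pipeline.yaml --outdir out/
seed: 1
simulation:
  n_genes: 2000
  frac_deg: 0.1
  baseline_mean: 100
  baseline_sigma: 0.25
  log2fc_distribution:
    min_abs: 2.0
thresholds:
  fc_min: 2.0
  q_max: 0.05
  rpkm_min: 1.0
  dev_fc_min: 2.0
proximity:
  n_permutations: 1000
  statistic: median_nn_distance
enrichment:
  min_term_size: 3
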