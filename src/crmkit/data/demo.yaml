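# Bundled demo: a fully synthetic run at zero noise, so every planted
# structure (temporal classes, SE loci, direct targets) is exactly
# recoverable from the outputs and the truth file.
seed: 0
outdir: crmkit_demo
synthetic:
  noise_sd: 0.0      # noiseless coverage track
  dispersion: 0.005  # near-Poisson counts
  mean_range: [200.0, 2000.0]
params:
  qc_min_genes: 50   # the synthetic matrix has 300 genes, not a transcriptome
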