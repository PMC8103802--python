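# Bundled toy study: three founders, two germplasm pools of six
# accessions (4 officinarum + 2 robustum vs 6 spontaneum) and one
# modern cultivar (9 A : 2 B : 1 C), on a 15-kb noise-free segment.
seed: 1
sim:
  genome_length: 15000
  n_genes: 6
  gene_length: 900
  within_pool_theta: 0.0
  error_rate: 0.0
  depth_mean: 100.0
  depth_dispersion: 0.0
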