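# Bundled synthetic study at reduced scale: fast, fully featured, seeded.
outdir: results/synthetic_fixture
seed: 20260930
synth:
  n_ppi_nodes: 800
  attach_m: 3
  n_diabetes: 160
  n_dr: 50
  n_common: 30
  n_lncrna: 150
  cerna_density: 2.0
  n_case: 25
  n_control: 5
  de_fraction: 0.1
  effect_log2fc: 1.5
  noise_sd: 0.4
  n_planted_cliques: 3
  clique_size_range: [6, 9]
  n_snps: 120
hub_k: 50
top_n_modules: 5
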