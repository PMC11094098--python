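# Bundled demo profile: three planted populations, planted focal-gene
# programs, planted keywords and ligand-receptor channels, at a size
# that runs end-to-end in a couple of minutes on one CPU.
seed: 7

synth:
  n_cells_per_population: 200
  n_noise_genes: 1900
  nb_dispersion: 2.0
  coupling: 0.8
  n_samples: 2

qc: {}

cluster:
  theta: 100.0
  n_hvg: 2000
  n_pcs: 30
  k_neighbors: 20
  resolution: 1.0

markers:
  min_pct: 0.5
  logfc_min: 0.25
  anchor: GAMs.mk0

assoc:
  focal: SORL1
  bins: auto
  n_trees: 300
  n_perm: 25
  perm_trees: 100

keywords:
  vocab_size: 2000
  words_per_doc: 40
  top_k: 10

comm:
  n_perm: 100
  n_decoys: 8
  split_group: GAMs
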