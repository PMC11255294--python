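simulate:
  cell_types: [ILC2, ILC1]
  n_cells: [150, 150]
  n_genes: 1000
  n_peaks: 1000
  signature_size_genes: 30
  signature_size_peaks: 50
  rna_effect: 4.0
  atac_effect: 4.0
  n_motifs: 20
  motif_size: 50
  seed: 7
qc:
  thresholds:
    rna_min: 100
    rna_max: 1000000
    atac_min: 10
    atac_max: 1000000
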