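{
  "mapped_scaffolds": 14336,
  "multi_marker_scaffolds": 4859,
  "intra_split_scaffolds": 26,
  "inter_split_scaffolds": 164,
  "splits_total": 219,
  "splits_at_contig_joins": 184,
  "gene_models_mapped": 17079,
  "gene_models_on_multi_marker": 6099,
  "gene_models_on_split": 330,
  "gene_models_with_internal_split": 100,
  "glauca_comparisons": 14112,
  "glauca_homologous": 13084,
  "abies_array_comparisons": 353,
  "abies_array_nonhomologous": 11,
  "cluster_samples": {"cluster1": 314, "cluster2": 270, "cluster3": 842},
  "consensus_markers": 21056,
  "consensus_scaffolds": 14336
}
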