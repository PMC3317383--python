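# End-to-end FoxO3 analysis over the packaged fixtures.
query_fasta: foxo3_human_synthetic.fasta
alignment: foxo3_orthologs_synthetic.aln
alignment_dialect: clustal
site_table: foxo3_site_scores.tsv
ev_table: foxo3_ev_sites.tsv
kinase_table: foxo3_kinases.tsv
methyl_callsets: foxo3_methyl_callsets.tsv
min_agree: 2
domains: foxo3_domains.tsv
transfer_src_fasta: foxo1_mouse_synthetic.fasta
transfer_src_sites: [248, 250]
neighbor_radius: 5
params:
  phos_threshold: 0.5
  sa_min: 0.5
  epsilon: 0.1
  min_fraction: 1.0
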