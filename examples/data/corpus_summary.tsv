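quantity	value
total_reads	330297
total_bases	263200000
genome_size	1600000000
max_sre_support	548
sampled_fraction_pct	16.4
ssr_count	50206
gene_loci	439
gene_model_bases	7200000
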