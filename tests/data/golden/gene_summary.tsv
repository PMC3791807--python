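gene_id	n_1	n_2	n_3	n_4	n_3or4	n_5	n_other	n_p5_with_depth	mean_ratio_g2	covered_positions	snp_per_covered_kb
gene00001	0	0	1	0	0	1	0	1	0.601942	300	6.66667
gene00002	0	1	0	1	0	3	0	3	0.766444	300	16.6667
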