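contig	pos	ref	diploid_gt	tetraploid_gt	category	subgenome_origin	depth_g1	depth_g2	ratio_g2
gene00001	156	A	A/A	A/T	3	G1	NA	NA	NA
gene00001	273	T	G/G	G/T	5	G1	41	62	0.601942
gene00002	36	C	T/T	C/T	5	G1	16	75	0.824176
gene00002	88	T	G/G	T/T	2	n/a	NA	NA	NA
gene00002	127	G	T/T	G/T	5	G1	30	75	0.714286
gene00002	128	C	A/A	A/C	5	G1	22	70	0.76087
gene00002	244	T	T/T	C/T	4	G2	NA	NA	NA
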