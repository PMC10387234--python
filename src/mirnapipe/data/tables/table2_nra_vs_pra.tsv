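mirna_id	tpm_a	tpm_b	direction	log2fc
hsa-miR-362-5p	0.129890228	0.01	up	3.69922099
hsa-miR-708-3p	0.03360368	0.01	up	1.74861923
hsa-miR-6741-5p	0.01	0.810320123	down	-6.340420063
hsa-miR-3127-5p	0.01	0.946841448	down	-6.565050956
hsa-miR-6855-5p	0.01	0.184964376	down	-4.20917553
hsa-miR-187-3p	0.01	0.052250413	down	-2.385442428
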