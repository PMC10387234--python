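mirna_id	tpm_a	tpm_b	direction	log2fc
hsa-miR-362-5p	0.151394564	0.01	up	3.920241501
hsa-miR-4429	0.097494943	0.283607444	down	-1.540496108
hsa-miR-378e	0.01	0.539587039	down	-5.753783791
hsa-miR-302c-3p	0.01	0.122616762	down	-3.616084305
hsa-miR-378g	0.01	0.122423043	down	-3.613803223
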