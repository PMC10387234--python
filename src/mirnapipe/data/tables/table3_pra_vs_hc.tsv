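mirna_id	tpm_a	tpm_b	direction	log2fc
hsa-miR-6855-5p	0.239985	0.01	up	4.584875185
hsa-miR-187-3p	0.148407	0.01	up	3.891482393
hsa-miR-371a-5p	0.108831	0.01	up	3.444023416
hsa-miR-302a-3p	0.017142	0.360278	down	-4.393518258
hsa-miR-320e	0.005714	0.919273	down	-7.329863854
hsa-miR-218-5p	0.01	0.911274	down	-6.509812533
hsa-miR-378e	0.01	0.720331	down	-6.170588065
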