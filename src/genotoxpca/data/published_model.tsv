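# Fixed-coefficient 4-gene projection published for out-of-sample scoring.
# published_cutoff=-0.507
gene	pc1_loading	pc2_loading	mu	sigma
Bax	-0.501	0.516	0.320	0.790
Btg2	-0.500	0.202	0.262	0.946
Ccng1	-0.516	0.079	0.562	1.166
Cdkn1a	-0.483	-0.828	0.402	1.352
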