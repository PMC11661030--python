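symbol	gene_name	gene_id
Aen	apoptosis enhancing nuclease	361594
Bax	BCL2 associated X, apoptosis regulator	24887
Btg2	BTG anti-proliferation factor 2	29619
Ccnf	cyclin F	117524
Ccng1	cyclin G1	25405
Cdkn1a	cyclin-dependent kinase inhibitor 1A	114851
Gdf15	growth differentiation factor 15	29455
Lrp1	LDL receptor related protein 1	299858
Mbd1	methyl-CpG binding domain protein 1	291439
Phlda3	pleckstrin homology-like domain, family A, member 3	363989
Plk2	polo-like kinase 2	83722
Tubb4b	tubulin, beta 4B class IVb	296554
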