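gene	gene_name	log2fc	fpkm_ko	fpkm_wt	binding_site	fdr
Bhmt	betaine-homocysteine methyltransferase	-6.7	0.3	34.0	Intergenic	1e-05
Mmel1	membrane metallo-endopeptidase-like 1	-5.1	0.3	9.1	-	1e-05
Ssu2	ssu-2 homolog (C. elegans)	-4.2	0.3	6.2	-	1e-05
Slc38a3	solute carrier family 38, member 3	-3.2	1.0	10.1	Intron 1	1e-05
Lrp8	low density lipoprotein receptor-related protein 8, apolipoprotein e receptor	-3.1	1.5	13.4	Intron 1	1e-05
Them5	thioesterase superfamily member 5	-2.3	0.4	2.2	-	1e-05
Cabp1	calcium binding protein 1	-1.9	0.9	4.2	Intron 1	1e-05
Tspan11	tetraspanin 11	-1.9	0.9	3.1	Intron 2	1e-05
Lrp11	low density lipoprotein receptor-related protein 11	-1.6	1.9	5.8	Intron 1	1e-05
Abca7	ATP-binding cassette, sub-family A (ABC1), member 7	-1.6	1.6	4.9	Exon	1e-05
Stx11	syntaxin 11	-1.4	1.3	3.4	-	1e-05
Adrb2	adrenergic receptor, beta 2	-1.3	1.3	3.0	-	1e-05
Ctnna2	catenin (cadherin associated protein), alpha 2	-1.2	1.0	2.2	Intron 1	1e-05
Nipal1	NIPA-like domain containing 1	-1.1	1.2	2.6	-	1e-05
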