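gene	gene_name	log2fc	site_index	location	tss_kb	ERE	NR5A	fdr
Slc38a3	solute carrier family 38, member 3	-3.2	0	intron 4	9.1	-	-	0.01
Lrp8	low density lipoprotein receptor-related protein 8, apolipoprotein e receptor	-3.1	0	intron 2	9.0	-	+	0.01
Cst8	cystatin 8 (cystatin-related epididymal spermatogenic)	-2.3	0	intron 2	2.8	+	+	0.01
Nrn1	neuritin 1	-2.3	0	downstream gene	224	-	+	0.01
Sgk1	serum/glucocorticoid regulated kinase 1	-2.1	0	intergenic	-38	-	+	0.01
Gsg1l	GSG1-like	-2.1	0	intron 2	113	+	x2	0.01
Dpysl4	dihydropyrimidinase-like 4	-2.1	0	upstream gene	-62	+	+	0.01
Cabp1	calcium binding protein 1	-1.9	0	intron 1	2.7	-	-	0.01
Tspan11	tetraspanin 11	-1.9	0	downstream gene	94	-	-	0.01
Enpp6	ectonucleotide pyrophosphatase/phosphodiesterase 6	-1.8	0	intergenic	-3.5	-	+	0.01
Fkbp5	FK506 binding protein 5	-1.7	1	intergenic	-22	+	x3	0.01
Fkbp5	FK506 binding protein 5	-1.7	2	intron 3	54	-	x3	0.01
Dsc2	desmocollin 2	-1.7	0	intron 1	0.7	+	+	0.01
Crybb1	crystallin, beta B1	-1.7	0	intergenic	-1.4	+	+	0.01
Txndc2	thioredoxin domain containing 2 (spermatozoa)	-1.6	1	upstream gene	-62	-	x3	0.01
Txndc2	thioredoxin domain containing 2 (spermatozoa)	-1.6	2	intergenic	-5.3	-	+	0.01
Fbn2	fibrillin 2	-1.6	0	intron 2	2.3	+	+	0.01
Lockd	lncRNA downstream of Cdkn1b	-1.6	0	intergenic	25	-	x2	0.01
Aif1l	allograft inflammatory factor 1-like	-1.5	0	intron 2	4.5	-	+	0.01
Parvb	parvin, beta	-1.5	0	intron 1	36	-	+	0.01
Tpst2	protein-tyrosine sulfotransferase 2	-1.4	0	intron 1	22	+	x2	0.01
Ddah1	dimethylarginine dimethylaminohydrolase 1	-1.3	0	intron 1	47	+	-	0.01
Mrap	melanocortin 2 receptor accessory protein	-1.3	0	intergenic	-2.4	-	+	0.01
Ctnna2	catenin (cadherin associated protein), alpha 2	-1.2	1	intergenic	-192	x2	-	0.01
Ctnna2	catenin (cadherin associated protein), alpha 2	-1.2	2	intron 1	71	+	+	0.01
Hao2	hydroxyacid oxidase 2	-1.1	1	intergenic	-39	-	+	0.01
Hao2	hydroxyacid oxidase 2	-1.1	2	intron 1	2.6	-	-	0.01
Gpr37	G protein-coupled receptor 37	-1.1	0	intergenic	239	-	x3	0.01
Ttyh2	tweety family member 2	-1.0	0	intron 3	16	-	x2	0.01
Fzd1	frizzled class receptor 1	-1.0	0	intergenic	262	-	+	0.01
Nek6	NIMA (never in mitosis gene a)-related expressed kinase 6	-1.0	0	intergenic	-13	-	-	0.01
Slc6a6	solute carrier family 6 (neurotransmitter transporter, taurine), member 6	-1.0	0	intergenic	-37	+	-	0.01
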