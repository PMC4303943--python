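locus	gene_symbol	gene_name	allele	cds_position	protein_position	aa_change	codon_change	sift_prediction	sift_score	colocated_variation
WAG/OXYS-1.1	Hps5	Hermansky-Pudlak syndrome 5	C	667	223	R/G	Aga/Gga	tolerated	0.46	-
WAG/OXYS-1.1	Hps5	Hermansky-Pudlak syndrome 5	T	188	63	R/K	aGg/aAg	tolerated	0.25	-
WAG/OXYS-1.1	Cic	capicua transcriptional repressor	A	1517	506	C/Y	tGc/tAc	tolerated	0.08	-
WAG/OXYS-1.1	Arhgap33	RhoGTPase activating protein 33	T	3466	1156	D/N	Gat/Aat	deleterious	0	-
WAG/OXYS-1.1	Lin37	lin-37 homolog (Caenorhabditis elegans)	A	547	183	P/S	Cca/Tca	tolerated	0.18	-
WAG/OXYS-1.1	Cebpg	CCAAT/enhancer binding protein (C/EBP), gamma	T	410	137	S/N	aGc/aAc	tolerated	0.45	-
WAG/OXYS-1.1	Nudt19	nudix (nucleoside diphosphate linked moiety X)-type motif 19	C	1015	339	S/G	Agc/Ggc	tolerated	0.42	-
WAG/OXYS-1.2	Ccp110	centriolar coiled coil protein 110 kDa	A	868	290	D/N	Gat/Aat	tolerated	0.17	rs197588212
WAG/OXYS-1.2	Gtf3c1	general transcription factor IIIC, polypeptide 1, alpha	A	6379	2127	R/C	Cgt/Tgt	-	-	rs8156681
WAG/OXYS-1.2	Gtf3c1	general transcription factor IIIC, polypeptide 1, alpha	C	5692	1898	T/A	Aca/Gca	tolerated	0.75	rs198509438
WAG/OXYS-1.2	Gtf3c1	general transcription factor IIIC, polypeptide 1, alpha	C	5021	1674	N/S	aAt/aGt	tolerated	0.74	rs106585674
WAG/OXYS-1.2	Rabep2	rabaptin, RAB GTPase binding effector protein 2	C	1007	336	I/T	aTc/aCc	tolerated	1	rs8153744
WAG/OXYS-1.2	Aldoa	aldolase A, fructose-bisphosphate	C	493	165	M/V	Atg/Gtg	tolerated	0.58	rs8160964
WAG/OXYS-1.2	Inpp5f	inositol polyphosphate-5-phosphatase F	C	3075	1025	L/F	ttG/ttC	tolerated	0.44	-
WAG/OXYS-1.2	Psat1	phosphoserine aminotransferase 1	T	316	106	A/T	Gct/Act	tolerated	0.61	-
WAG/OXYS-1.2	Tjp2	tight junction protein 2	T	767	256	R/H	cGc/cAc	tolerated	0.59	rs198995028
WAG/OXYS-1.2	Ak3	adenylate kinase 3	T	368	123	L/Q	cTa/cAa	tolerated	0.66	rs197195051
WAG/OXYS-1.2	Ric1	RAB6A GEF complex partner 1	G	229	77	N/D	Aac/Gac	tolerated	1	rs197794754
WAG/OXYS-1.2	RGD1311595	similar to KIAA2026 protein	C	2613	871	I/M	atA/atG	tolerated	1	rs198237726
WAG/OXYS-1.2	Sfxn3	sideroflexin 3	A	927	309	N/K	aaC/aaA	tolerated	0.92	rs8163692
WAG/OXYS-1.2	Nolc1	nucleolar and coiled-body phosphoprotein 1	A	421	141	E/K	Gag/Aag	tolerated	0.61	rs8165446
WAG/OXYS-1.2	Pdcd11	programmed cell death 11	C	3005	1002	I/T	aTc/aCc	tolerated	1	-
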