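mirna_id	chrom	strand	rna_t	meth_t	ac_t	fc_LvP	star_LvP	fc_Lv5Aza	star_Lv5Aza	fc_Pv5Aza	star_Pv5Aza
MIRLET7c	21	+	34.26	-0.14	3.07	54.948	*	0.986		1.505
MIR141	12	+	7.2	-0.46	4.31	2.928	*	2.235	*	1.110
MIR15b	3	+	11.41	-4.65	-4.02	2.071	*	0.616		0.986
MIR16-2	3	+	10.52	-3.6	-2.54	2.713	*	1.424	*	0.742
MIR423	17	+	8.91	-0.81	2.39	4.857	*	0.774		2.445	*
MIR491	9	+	9.03	-2.08	0.83	5.352	*	1.117		1.301
MIR615	12	+	4.03	-3.45	5.5	1.9E+03	*	1.231		32.672	*
MIR618	12	-	4.18	2.44	5.73	4.1E+02	*	1.945	*	1.385
MIR99a	21	+	26.52	-2.9	3.72	2.329	*	1.035		0.908
MIR130a	11	+	-7.19	-1.92	-3.85	0.004	*	2.532	*	1.102
MIR135b	1	-	-3.93	2.8	-7.82	0.003	*	0.337		1.828
MIR137	1	-	-3.81	1.19	-3.41	0.016	*	2.173		5.897
MIR196b	7	-	-11.26	2.07	-5.05	0.356	*	1.591	*	0.829
MIR205	1	+	-26.47	2.37	-12.09	1.2E-05	*	1.1E+02	*	1.659
MIR21	17	+	-21.68	13.78	-12.98	0.637	*	2.362	*	3.272	*
MIR24-1	9	+	-5.64	3.73	-0.27	0.057	*	1.569	*	1.231
MIR31	9	-	-2.79	-9.75	-3.04	1.7E-06	*	1.357		0.959
MIR376a-2	14	+	-5.98	2.96	2.59	0.020	*	4.857		2.888
MIR424	X	-	-3.94	1.95	-2.56	0.259	*	0.883		4.287	*
MIR654	14	+	-5.42	2.57	4.14	0.136	*	1.357		0.295	*
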