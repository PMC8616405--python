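orf_id	aa_length	strand	age_my	species_count	phastcons	prom_score	prom_dist	kozak_score	n_reads	breadth_pct	flag_polyriboseq	flag_proteomics	total_elms	distinct_types	elm_score	tm_signal	disorder	blastp_note
ORF682	60	+	40	3	0.954	0.96	-246	0.643	59	55		yes	2	2	83		disordered	Scr, Dfd
ORFas357	108	-	27	8	0.776	0.85	-191	0.874	8	46			14	8	144		ordered
ORFas712	215	-	14	5	0.718	0.98	-23	0.538	6	45			32	13	184		ordered
ORFas418	88	-	10	5	0.459	0.96	-143	0.448	5	58			13	8	144		18% disordered
ORFas87	46	-	27	5	0.623	0.81	-47	0.755	97	54			5	4	188		ordered
ORFas784	49	-	14	6	0.920	0.93	-84	0.776	53	76			4	4	220		ordered
ORFas430	51	-	10	4	0.921	0.93	-16	0.916	90	82			16	10	936		unclear
ORFas88	194	-	10	5	0.958	1.00	-232	0.881	193	60			18	12	410		ordered
ORF942	38	+	40	6	0.986	0.81	-48	0.434	77	98		yes	5	4	195		disordered
ORF941	37	+	10	5	0.984	0.81	-171	0.490	55	97		yes	2	2	228		disordered
ORF268	71	+	10	5	0.755	0.96	-278	0.594	123	88	yes	yes	15	10	347	1 Signal peptide, 1 TMhelix	ordered	5'-Ubx
ORFas449	61	-	40	5	0.699	0.90	-121	0.944	9	77			8	6	234		disordered
ORFas450	36	-	40	10	0.995	0.99	-9	0.986	6	51			1	1	13		32% disordered
ORFas803	116	-	10	4	0.544	0.92	-79	0.503	10	64			14	9	167		ordered
ORFas452	75	-	10	3	0.462	0.92	-167	0.825	8	60			15	9	196	1 TMhelix	7% disordered
ORF211	48	+	10	3	0.659	0.84	-8	0.643	6	53			10	9	989		36% disordered
ORFas137	113	-	10	5	0.616	0.94	-72	0.699	9	65		yes	22	10	197		ordered
ORF861	41	+	10	5	0.765	0.88	-202	0.427	14	89		yes	8	8	432		ordered
ORFas875	38	-	10	5	0.906	0.95	-165	0.434	185	98			1	1	38		ordered
ORFas165	62	-	14	6	0.936	0.93	-141	0.727	82	53			6	3	74		ordered
ORF172	80	+	10	5	0.607	0.97	-85	0.790	12	81			10	8	233		ordered
ORF497	109	+	40	9	0.480	0.91	-189	0.839	7	68			17	9	233		ordered
ORFas170	68	-	10	4	0.511	1.00	-96	0.434	7	91			12	10	302		ordered
ORF847	70	+	10	4	0.490	0.88	-130	0.427	5	65			28	10	461		14% disordered
ORFas175	114	-	40	11	0.628	0.81	-177	0.503	16	64			14	9	132		ordered
ORF842	34	+	10	5	0.815	0.89	-118	0.762	5	79			11	8	465		unclear
ORFas894	152	-	40	7	0.617	0.93	-42	0.497	93	59			13	9	180		6% disordered
ORFas538	57	-	10	5	0.974	0.93	-97	0.650	79	94			5	5	1177		unclear
ORFas545	47	-	10	5	0.600	0.84	-36	0.727	7	42			4	4	247		ordered
ORFas561	72	-	10	3	0.647	0.82	-112	0.455	8	58	yes	yes	8	6	168	1 TMhelix	25% disordered
ORFas200	54	-	10	5	0.484	0.81	-278	0.441	6	100	yes	yes	6	5	141		ordered
ORFas566	80	-	10	5	0.682	0.98	-265	0.734	13	90		yes	17	11	409	1 TMhelix	ordered
ORF459	46	+	10	4	0.571	0.85	-205	0.713	6	100			3	3	131		48% disordered
ORFas567	32	-	10	5	0.582	0.88	-47	0.580	8	86		yes	7	7	235		ordered
ORF817	49	+	10	4	0.595	0.84	-251	0.657	8	50	yes	yes	3	3	66		37% disordered
ORF52	242	+	10	5	0.431	0.98	-93	0.629	51	50	yes	yes	30	12	120		5% disordered
ORF393	241	+	10	5	0.442	0.89	-159	0.699	27	63			30	13	153		ordered
ORF727	53	+	10	4	0.539	0.93	-210	0.552	11	96		yes	5	4	151		disordered
ORFas1007	30	-	10	5	0.935	0.98	-105	0.832	39	93			5	5	287		ordered
ORFas293	100	-	10	4	0.523	0.95	-134	0.427	187	84			9	5	65	1 TMhelix	ordered
ORFas294	34	-	10	2	0.691	0.95	-112	0.441	69	66			4	4	161		ordered
ORF389	51	+	14	3	0.499	0.99	-129	0.755	40	46			12	8	352		67% disordered
ORFas650	75	-	10	5	0.839	1.00	-234	0.538	118	54			6	5	965		ordered
ORF44	274	+	40	4	0.906	0.81	-100	0.818	227	45	yes		125	17	522		61% disordered
ORFas1009	75	-	10	4	0.938	0.98	-181	0.762	79	47			0	0	0	1 TMhelix	ordered
ORFas296	49	-	10	5	0.697	0.84	-1	0.853	17	96			7	6	135		ordered
ORFas1029	39	-	14	5	0.632	0.90	-9	0.965	6	58			1	1	31		ordered
ORF358	133	+	40	8	0.484	0.86	-160	0.748	43	47	yes		10	9	100		ordered
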