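contig	annotation	pos	ref	var	freq_sb	freq_ac	effect	stratum
SS2U026955	Keratin type II cytoskeletal 3	300	A	T	0.000	0.984	synonymous	UNI
SS2U026955	Keratin type II cytoskeletal 3	309	G	A	0.000	0.996	synonymous	UNI
SS2U033960	Cysteine sulfinic acid decarboxylase	192	C	G	0.000	1.000	5prime	UNI
SS2U033960	Cysteine sulfinic acid decarboxylase	416	G	T	0.000	0.961	G to V	UNI
SS2U033960	Cysteine sulfinic acid decarboxylase	945	C	A	0.004	0.956	synonymous	UNI
SS2U043396	Eukaryotic translation initiation factor 2-alpha kinase 1	134	A	G	0.000	1.000	5prime	UNI
SS2U043886	Transcription cofactor HES-6	1308	T	C	0.000	1.000	5prime	UNI
SS2U044339	Intraflagellar transport protein 52 homolog	479	T	C	0.021	1.000	D to G	UNI
SS2U045168	Putative Peptide prediction	1275	G	A	0.000	1.000	3prime	UNI
SS2U045328	E3 ubiquitin-protein ligase DTX3L	388	G	A	0.000	0.977	synonymous	UNI
SS2U045990	Low-density lipoprotein receptor-related protein 1	135	T	C	0.000	0.969	synonymous	UNI
SS2U048125	Transmembrane protein 131-like	480	G	A	0.000	1.000	synonymous	UNI
SS2U052747	Uridine 5'-monophosphate synthase	914	G	A	0.000	0.951	synonymous	UNI
SS2U054542	Mediator of RNA polymerase II transcription subunit 20	474	C	T	0.027	0.995	synonymous	UNI
SS2U056193	SUMO-conjugating enzyme UBC9	96	A	T	0.000	1.000	3prime	UNI
SS2U057101	ETS domain-containing protein Elk-3	440	C	G	0.000	1.000	3prime	UNI
SS2U058860	Voltage-dependent anion-selective channel protein 2	681	G	T	0.000	1.000	3prime	UNI
SS2U000399	Insulin-like growth factor-binding protein 7	598	C	A	1.000	0.000	3prime	UNI
SS2U004484	Titin	387	G	A	0.990	0.010	synonymous	UNI
SS2U026826	L-asparaginase	363	C	T	1.000	0.000	H to Y	UNI
SS2U026955	Keratin type II cytoskeletal 3	116	C	A	0.996	0.031	T to N	UNI
SS2U026955	Keratin type II cytoskeletal 3	264	C	T	0.970	0.008	synonymous	UNI
SS2U026955	Keratin type II cytoskeletal 3	317	C	T	1.000	0.002	T to M	UNI
SS2U033960	Cysteine sulfinic acid decarboxylase	363	C	T	1.000	0.025	5prime	UNI
SS2U033960	Cysteine sulfinic acid decarboxylase	387	C	T	1.000	0.030	synonymous	UNI
SS2U033960	Cysteine sulfinic acid decarboxylase	657	T	C	0.990	0.031	synonymous	UNI
SS2U034322	Cyclin-C	1094	A	G	1.000	0.000	3prime	UNI
SS2U034431	Dolichyl-diphosphooligosaccharide--protein glycosyltransferase subunit 2	436	G	A	0.992	0.000	G to S	UNI
SS2U036025	Nuclear receptor coactivator 4	36	G	A	1.000	0.043	5prime	UNI
SS2U040590	Glutamyl-tRNA(Gln) amidotransferase subunit A homolog	478	G	A	0.972	0.000	synonymous	UNI
SS2U045606	Superkiller viralicidic activity 2-like 2	500	C	T	1.000	0.000	synonymous	UNI
SS2U047816	Squalene synthase	1139	G	A	1.000	0.029	synonymous	UNI
SS2U048063	Lysine-specific demethylase NO66	669	C	T	1.000	0.000	synonymous	UNI
SS2U050394	UPF0542 protein C5orf43 homolog	596	G	A	1.000	0.000	synonymous	UNI
SS2U050880	Transmembrane protein 131-like	901	C	T	1.000	0.000	A to V	UNI
SS2U052076	Eukaryotic translation initiation factor 3 subunit A	824	C	T	1.000	0.031	synonymous	UNI
SS2U053417	RNA polymerase-associated protein LEO1	454	G	A	1.000	0.049	synonymous	UNI
SS2U054333	Scaffold attachment factor B2	382	G	A	0.999	0.000	V to M	UNI
SS2U054705	Cell division protein kinase 4	122	A	G	0.971	0.000	3prime	UNI
SS2U054965	DNA-directed RNA polymerase I subunit RPA12	106	G	A	1.000	0.000	5prime	UNI
SS2U054965	DNA-directed RNA polymerase I subunit RPA12	411	T	G	1.000	0.000	synonymous	UNI
SS2U055120	Chromatin modification-related protein MEAF6	350	A	C	1.000	0.000	H to P	UNI
SS2U055153	Complexin-1	1191	C	A	1.000	0.031	3prime	UNI
SS2U057635	Mitogen-activated protein kinase 14B	1370	A	T	1.000	0.026	3prime	UNI
SS2U058169	Transmembrane protein 50A	1214	C	G	0.973	0.000	3prime	UNI
SS2U058802	Signal recognition particle 54 kDa protein	607	T	A	0.969	0.000	C to S	UNI
SS2U004839	Actin alpha sarcomeric/cardiac	550	A	C	0.015	0.999	3prime	REP
SS2U021298	28S ribosomal protein S18a mitochondrial	462	A	C	0.000	1.000	synonymous	REP
SS2U041264	Apoptosis-inducing factor 1 mitochondrial	341	C	T	0.000	0.952	synonymous	REP
SS2U054211	Cytoplasmic dynein 1 intermediate chain 2	136	T	C	0.018	0.974	synonymous	REP
SS2U054362	Q08CA8 Dynein cytoplasmic 1 intermediate chain 2	945	A	G	0.000	1.000	synonymous	REP
SS2U055923	Bystin	1623	A	C	0.000	0.983	3prime	REP
SS2U058758	Protein S100-A1	253	C	T	0.000	0.984	synonymous	REP
SS2U059000	Isocitrate dehydrogenase [NADP] mitochondrial	1654	T	C	0.000	0.975	3prime	REP
SS2U059146	60S ribosomal protein L36	263	T	G	0.009	1.000	synonymous	REP
SS2U059146	60S ribosomal protein L36	470	A	C	0.009	1.000	synonymous	REP
SS2U036667	Heterogeneous nuclear ribonucleoprotein K	813	C	T	1.000	0.022	5prime	REP
SS2U042873	RNA polymerase-associated protein LEO1	460	G	A	1.000	0.000	synonymous	REP
SS2U058455	Adenylosuccinate lyase	1616	C	T	1.000	0.000	3prime	REP
SS2U058906	Mid1-interacting protein 1-like	350	G	T	0.985	0.000	E to D	REP
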