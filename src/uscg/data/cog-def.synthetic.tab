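COG0008	J	Glutamyl- or glutaminyl-tRNA synthetase	gltX			
COG0012	J	Ribosome-binding ATPase YchF	ychF			
COG0013	J	Alanyl-tRNA synthetase	alaS			
COG0016	J	Phenylalanyl-tRNA synthetase alpha subunit	pheS			
COG0017	J	Aspartyl/asparaginyl-tRNA synthetase	asnC			
COG0018	J	Arginyl-tRNA synthetase	argS			
COG0024	J	Methionine aminopeptidase	map			
COG0030	J	16S rRNA A1518 dimethyltransferase	rsmA			
COG0048	J	Ribosomal protein S12	rpsL			
COG0049	J	Ribosomal protein S7	rpsG			
COG0050	J	Translation elongation factor Tu	tuf			
COG0052	J	Ribosomal protein S2	rpsB			
COG0060	J	Isoleucyl-tRNA synthetase	ileS			
COG0072	J	Phenylalanyl-tRNA synthetase beta subunit	pheT			
COG0080	J	Ribosomal or translation-associated protein 0080	rtp0080			
COG0081	J	Ribosomal or translation-associated protein 0081	rtp0081			
COG0085	K	DNA-directed RNA polymerase, beta subunit	rpoB			
COG0087	J	Ribosomal or translation-associated protein 0087	rtp0087			
COG0088	J	Ribosomal or translation-associated protein 0088	rtp0088			
COG0090	J	Ribosomal or translation-associated protein 0090	rtp0090			
COG0091	J	Ribosomal or translation-associated protein 0091	rtp0091			
COG0092	J	Ribosomal or translation-associated protein 0092	rtp0092			
COG0093	J	Ribosomal or translation-associated protein 0093	rtp0093			
COG0094	J	Ribosomal or translation-associated protein 0094	rtp0094			
COG0096	J	Ribosomal or translation-associated protein 0096	rtp0096			
COG0097	J	Ribosomal or translation-associated protein 0097	rtp0097			
COG0098	J	Ribosomal or translation-associated protein 0098	rtp0098			
COG0099	J	Ribosomal or translation-associated protein 0099	rtp0099			
COG0100	J	Ribosomal or translation-associated protein 0100	rtp0100			
COG0102	J	Ribosomal or translation-associated protein 0102	rtp0102			
COG0103	J	Ribosomal or translation-associated protein 0103	rtp0103			
COG0124	J	Histidyl-tRNA synthetase	hisS			
COG0130	J	tRNA pseudouridine synthase	truB			
COG0143	J	Methionyl-tRNA synthetase	metG			
COG0150	F	Phosphoribosylaminoimidazole synthetase	purM			
COG0172	J	Seryl-tRNA synthetase	serS			
COG0180	J	Tryptophanyl-tRNA synthetase	trpS			
COG0184	J	Ribosomal or translation-associated protein 0184	rtp0184			
COG0185	J	Ribosomal or translation-associated protein 0185	rtp0185			
COG0186	J	Ribosomal or translation-associated protein 0186	rtp0186			
COG0197	J	Ribosomal or translation-associated protein 0197	rtp0197			
COG0200	J	Ribosomal or translation-associated protein 0200	rtp0200			
COG0201	U	Preprotein translocase subunit SecY	secY			
COG0202	K	DNA-directed RNA polymerase, alpha subunit	rpoA			
COG0215	J	Cysteinyl-tRNA synthetase	cysS			
COG0216	J	Peptide chain release factor 1	prfA			
COG0228	J	Ribosomal or translation-associated protein 0228	rtp0228			
COG0231	J	Translation elongation factor P	efp			
COG0233	J	Ribosome recycling factor	frr			
COG0238	J	Ribosomal or translation-associated protein 0238	rtp0238			
COG0244	J	Ribosomal protein L10	rplJ			
COG0250	K	Transcription antiterminator NusG	nusG			
COG0255	J	Ribosomal or translation-associated protein 0255	rtp0255			
COG0256	J	Ribosomal or translation-associated protein 0256	rtp0256			
COG0261	J	Ribosomal or translation-associated protein 0261	rtp0261			
COG0264	J	Ribosomal or translation-associated protein 0264	rtp0264			
COG0267	J	Ribosomal or translation-associated protein 0267	rtp0267			
COG0268	J	Ribosomal or translation-associated protein 0268	rtp0268			
COG0290	J	Translation initiation factor IF-3	infC			
COG0291	J	Ribosomal or translation-associated protein 0291	rtp0291			
COG0292	J	Ribosomal or translation-associated protein 0292	rtp0292			
COG0335	J	Ribosomal or translation-associated protein 0335	rtp0335			
COG0343	J	tRNA-guanine transglycosylase	tgt			
COG0361	J	Translation initiation factor IF-1	infA			
COG0495	J	Leucyl-tRNA synthetase	leuS			
COG0522	J	Ribosomal or translation-associated protein 0522	rtp0522			
COG0525	J	Valyl-tRNA synthetase	valS			
COG0532	J	Translation initiation factor IF-2	infB			
COG0533	O	tRNA A37 threonylcarbamoyltransferase	tsaD			
COG0541	U	Signal recognition particle GTPase	ffh			
COG0552	U	Signal recognition particle receptor	ftsY			
COG0691	O	tmRNA-binding protein SmpB	smpB			
COG1000	L	Synthetic marker family 1000	smf1000			
COG1001	J	Ribosomal or translation-associated protein 1001	rtp1001			
COG1002	J	Ribosomal or translation-associated protein 1002	rtp1002			
COG1003	J	Ribosomal or translation-associated protein 1003	rtp1003			
COG1004	J	Ribosomal or translation-associated protein 1004	rtp1004			
COG1005	J	Ribosomal or translation-associated protein 1005	rtp1005			
COG1006	J	Ribosomal or translation-associated protein 1006	rtp1006			
COG1007	H	Synthetic marker family 1007	smf1007			
COG1008	J	Ribosomal or translation-associated protein 1008	rtp1008			
COG1009	J	Ribosomal or translation-associated protein 1009	rtp1009			
COG1010	J	Ribosomal or translation-associated protein 1010	rtp1010			
COG1011	J	Ribosomal or translation-associated protein 1011	rtp1011			
COG1012	J	Ribosomal or translation-associated protein 1012	rtp1012			
COG1013	J	Ribosomal or translation-associated protein 1013	rtp1013			
COG1014	O	Synthetic marker family 1014	smf1014			
COG1015	J	Ribosomal or translation-associated protein 1015	rtp1015			
COG1016	J	Ribosomal or translation-associated protein 1016	rtp1016			
COG1017	J	Ribosomal or translation-associated protein 1017	rtp1017			
COG1018	J	Ribosomal or translation-associated protein 1018	rtp1018			
COG1019	J	Ribosomal or translation-associated protein 1019	rtp1019			
COG1020	J	Ribosomal or translation-associated protein 1020	rtp1020			
COG1021	F	Synthetic marker family 1021	smf1021			
COG1022	J	Ribosomal or translation-associated protein 1022	rtp1022			
COG1023	J	Ribosomal or translation-associated protein 1023	rtp1023			
COG1024	J	Ribosomal or translation-associated protein 1024	rtp1024			
COG1025	J	Ribosomal or translation-associated protein 1025	rtp1025			
COG1026	J	Ribosomal or translation-associated protein 1026	rtp1026			
COG1027	J	Ribosomal or translation-associated protein 1027	rtp1027			
COG1028	L	Synthetic marker family 1028	smf1028			
COG1029	J	Ribosomal or translation-associated protein 1029	rtp1029			
COG1030	J	Ribosomal or translation-associated protein 1030	rtp1030			
COG1031	J	Ribosomal or translation-associated protein 1031	rtp1031			
COG1032	J	Ribosomal or translation-associated protein 1032	rtp1032			
COG1033	J	Ribosomal or translation-associated protein 1033	rtp1033			
COG1034	J	Ribosomal or translation-associated protein 1034	rtp1034			
COG1035	H	Synthetic marker family 1035	smf1035			
COG1036	J	Ribosomal or translation-associated protein 1036	rtp1036			
COG1037	J	Ribosomal or translation-associated protein 1037	rtp1037			
COG1038	J	Ribosomal or translation-associated protein 1038	rtp1038			
COG1039	J	Ribosomal or translation-associated protein 1039	rtp1039			
COG1040	J	Ribosomal or translation-associated protein 1040	rtp1040			
COG1041	J	Ribosomal or translation-associated protein 1041	rtp1041			
COG1042	O	Synthetic marker family 1042	smf1042			
COG1043	J	Ribosomal or translation-associated protein 1043	rtp1043			
COG1044	J	Ribosomal or translation-associated protein 1044	rtp1044			
COG1045	J	Ribosomal or translation-associated protein 1045	rtp1045			
COG1046	J	Ribosomal or translation-associated protein 1046	rtp1046			
COG1093	J	Translation initiation factor eIF-2A-like	sui1			
COG2202	TK	Signal transduction histidine kinase	barA			
COG3210	M	Large exoprotein involved in adhesion	fhaB			
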