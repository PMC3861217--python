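# Published non-synonymous SNPs fixed between the wMel-like and wMelCS-like
# Wolbachia clades. Nucleotide and amino-acid coordinates follow the wMel
# reference genome AE017196; gene descriptions follow its annotation.
# aa_pos is empty where the published table leaves the cell blank.
gene	symbol	description	nt_pos	nt_wmel	nt_wmelcs	aa_pos	aa_wmel	aa_wmelcs
WD0019		transcription antitermination protein NusG, putative	18552	A	G	191	Q	R
WD0024	rpoBC	DNA-directed RNA polymerase, beta/beta' subunit	26870	G	A	2060	E	K
WD0033		Piwi/Argonaute/Zwille siRNA-binding domain	36114	C	T	158	V	I
WD0036	prsA	ribose-phosphate pyrophosphokinase	39135	A	C	99	K	Q
WD0041		-	45207	A	G	12	M	T
WD0068		outer membrane protein TolC, putative	65076	A	G	122	N	S
WD0073		ankyrin repeat-containing protein	69287	A	G	298	T	A
WD0086	secD	protein-export membrane protein SecD	79898	G	A	91	T	I
WD0115		transposase, IS4 family	109211	T	G		STOP	E
WD0129		membrane protein CvpA, putative	118051	C	T	15	V	I
WD0130	ribE	riboflavin synthase, alpha subunit	118692	A	G	19	F	S
WD0131		-	119806	A	G	285	L	P
WD0190	mutS	DNA mismatch repair protein MutS	173865	C	T	50	G	R
WD0223		Rossmann-fold NAD(P)(+)-binding proteins; Bacterial NAD-glutamate dehydrogenase	203561	C	T	1233	V	I
WD0223		Rossmann-fold NAD(P)(+)-binding proteins; Bacterial NAD-glutamate dehydrogenase	204413	T	C	949	N	D
WD0262		RuvC_resolvase	248476	G	A	108	A	T
WD0292		prophage LambdaW1, ankyrin repeat domain protein	273138	A	G	40	S	P
WD0363		-	347096	C	T	52	Q	STOP
WD0400		ABC transporter, HlyB/MsbA family, putative	381187	T	C	143	I	T
WD0427	atpB	ATP synthase F0F, A subunit	409057	A	G	139	E	G
WD0433	pccA	propionyl-CoA carboxylase, alpha subunit	414527	G	A	246	T	M
WD0443		OTU-like cysteine protease	427731	C	T	119	R	C
WD0469		cytidine and deoxycytidylate deaminase family protein	452129	C	T	55	S	L
WD0513		RHS repeat-associated core domain	505589	G	A	56	T	I
WD0514		ankyrin repeat-containing protein	506438	C	A	255	A	S
WD0530	pyrH	uridylate kinase	517457	C	T	37	A	T
WD0562		transposase, truncation	547769	C	T	62	E	K
WD0610		helicase, SNF2 family	591593	C	G	126	Q	H
WD0614		O-methyltransferase	598213	G	A	483	D	N
WD0636		ankyrin repeat-containing prophage LambdaW1	628654	G	T	124	A	E
WD0638		Phage tail protein	630778	A	G	112	L	P
WD0639		prophage LambdaW5, baseplate assembly protein J	631303	T	C	201	M	V
WD0666	rplF	ribosomal protein L6	650962	C	T	23	S	N
WD0754		ankyrin repeat-containing protein	728880	T	C	48	E	G
WD0758		glutaredoxin family protein	732864	C	G	18	G	A
WD0766		ankyrin repeat-containing protein	739409	T	G	139	L	W
WD0766		ankyrin repeat-containing protein	739559	T	C	189	I	T
WD0813	proS	prolyl-tRNA synthetase	780933	G	C	196	G	R
WD0814	acpS	holo-(acyl-carrier-protein) synthase	781622	A	G	4	S	G
WD0838		-	803009	G	A	41	V	I
WD0838		-	805011	G	A	709	C	Y
WD0839	uvrB	excinuclease ABC, subunit B	805888	G	C	524	Q	E
WD0867	purH	phosphoribosylaminoimidazolecarboxamide formyltransferase/IMP cyclohydrolase	838894	A	G	260	E	G
WD0898		-	864943	C	A	2	L	F
WD1029	aspC	aspartate aminotransferase	989918	C	G	24	A	G
WD1044		-	1006175	G	A	33	G	D
WD1064	rpoH	heat shock sigma factor RpoH	1024202	A	G	42	N	D
WD1090	rpsA	ribosomal protein S1, putative	1048565	T	C	451	D	G
WD1137		PD-(D/E)XK nuclease family transposase	1089274	T	C	6	I	V
WD1140		PD-(D/E)XK nuclease family transposase	1091606	T	C	34	D	G
WD1200	priA	primosomal protein N	1147604	G	C	423	G	A
WD1216		sensor histidine kinase/response regulator	1164424	C	T	391	H	Y
WD1237	clpA	ATP-dependent Clp protease, ATP-binding subunit ClpA	1185021	G	A	667	A	T
WD1278		-	1220566	A	G	244	Y	C
WD1278		-	1220989	A	G	385	D	G
WD1292		ribonuclease, BN family	1232581	C	T	124	A	V
WD1297		lipolytic enzyme, GDSL family	1239247	C	T	181	R	H
WD1312		DsbA-like disulfide oxidoreductase	1253148	C	T	217	G	E
WD1318	infB	translation initiation factor IF-2	1260309	C	T	309	G	D
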