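Indiv	Type	Hpy	Ctry	Eth	Sex	Age	Hist	Anat	Stage
I_9709	EBV	N	Col	Lat	M	78	NA	B	IV
I_26163	EBV	N	Mex	Lat	M	72	I	B	IA
Subtotal	2	0
I_10845	MSI	Y	Col	Lat	F	56	I	A	IV
I_8012	MSI	N	Col	Lat	M	62	I	C	IV
I_13137	MSI	N	USA	Wht	M	68	D	NA	IB
I_20447	MSI	N	USA	Wht	M	82	NA	C	NA
Subtotal	4	1
I_13148	CIN	N	Col	Lat	F	37	D	A	IV
I_3755	CIN	N	Col	Lat	F	42	I	A	IIIB
I_7245	CIN	N	Col	Lat	F	64	I	A	IIIB
I_12808	CIN	N	Col	Lat	M	NA	NA	NA	IV
I_9278	CIN	N	Col	Lat	M	60	I	A	IV
I_9297	CIN	N	Col	Lat	M	60	M	C	IIIB
I_8164	CIN	N	Col	Lat	M	61	D	A	IIIB
I_9296	CIN	N	Col	Lat	M	67	M	A	IIB
I_26175	CIN	N	Mex	Lat	F	79	D	A/P	IIIC
I_26166	CIN	N	Mex	Lat	M	55	I	A/P	IIIB
I_26181	CIN	N	Mex	Lat	M	57	D	B/C	IIIC
I_13139	CIN	N	USA	Wht	F	74	D	A/P	NA
Subtotal	12	0
I_9715	GS	Y	Col	Lat	F	31	I	L/A	IIIB
I_19344	GS	Y	Col	Lat	F	32	NA	NA	IV
I_11981	GS	Y	Col	Lat	F	49	D	L	IB
I_19343	GS	Y	Col	Lat	F	50	NA	NA	IV
I_6579	GS	N	Col	Lat	F	56	I	A	IV
I_9299	GS	N	Col	Lat	M	47	I	B/A	IIB
I_9710	GS	N	Col	Lat	M	53	I	A	II
I_14885	GS	N	Col	Lat	M	78	I	A	IIB
I_26169	GS	N	Mex	Lat	F	57	D	A/P	IIIC
I_26167	GS	N	Mex	Lat	F	65	M	B	IV
I_26180	GS	N	Mex	Lat	M	59	D	A/P	IIIA
I_26171	GS	N	Mex	Lat	M	71	D	B/A	IV
I_26172	GS	N	Mex	Lat	M	76	D	A/P	IIIA
I_13141	GS	Y	USA	Lat	M	55	NA	B	NA
Subtotal	14	5
Total	32	6
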