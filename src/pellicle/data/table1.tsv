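species	strain	locus_kind	genotype	fragment_index	start	end	printed_length
P. laudensis	DSM28961	cwps	E	0	182887	201332	18445
P. laudensis	DSM28961	eps	V	0	74320	90617	16297
P. laudensis	T2A4	cwps	F	0	1999196	2023901	24705
P. laudensis	T2A4	eps	I	0	79289	93569	14280
P. laudensis	T2A6	cwps	F	0	1946019	1970724	24705
P. laudensis	T2A6	eps	VI	0	75286	94233	18947
P. laudensis	T2A7	cwps	F	0	2085468	2110175	24707
P. laudensis	T2A7	eps	I	0	107107	121389	14282
P. laudensis	T2A8	cwps	F	0	2017410	2042116	24706
P. laudensis	T2A8	eps	I	0	79288	93568	14280
P. laudensis	T2C1	cwps	F	0	2022619	2047325	24706
P. laudensis	T2C1	eps	IV	0	74431	91778	17347
P. laudensis	T2C6	cwps	F	0	1944846	1969552	24706
P. laudensis	T2C6	eps	VI	0	75286	94233	18947
P. laudensis	T2C9	cwps	F	0	2042130	2066835	24705
P. laudensis	T2C9	eps	I	0	79288	93568	14280
P. laudensis	T2D8	cwps	F	0	2054139	2078844	24705
P. laudensis	T2D8	eps	I	0	79288	93568	14280
P. laudensis	T2E11	cwps	F	0	150314	175019	24705
P. laudensis	T2E12	cwps	F	0	1944854	1969559	24705
P. laudensis	T2E12	eps	VI	0	75286	94233	18947
P. laudensis	T2E8	cwps	F	0	2054342	2079047	24705
P. laudensis	T2E8	eps	I	0	79289	93569	14280
P. laudensis	T2F10	cwps	F	0	1944795	1969499	24704
P. laudensis	T2F10	eps	VI	0	75286	94233	18947
P. laudensis	T2F2	cwps	F	0	1944847	1969552	24705
P. laudensis	T2F2	eps	VI	0	75286	94233	18947
P. laudensis	T2F8	cwps	F	0	2052966	2077672	24706
P. laudensis	T2F8	eps	I	0	79288	93568	14280
P. laudensis	T2G11	cwps	F	0	2048104	2072809	24705
P. laudensis	T2G11	eps	III	0	74437	90237	15800
P. laudensis	T2G3	cwps	F	0	2020537	2045242	24705
P. laudensis	T2G3	eps	IV	0	74430	91777	17347
P. laudensis	T2G5	cwps	F	0	2104178	2117025	12847
P. laudensis	T2G5	cwps	F	1	295724	307558	11834
P. laudensis	T2G5	eps	VII	0	76449	90201	13752
P. laudensis	T2H1	cwps	F	0	1999389	2024094	24705
P. laudensis	T2H1	eps	VI	0	75287	94234	18947
P. laudensis	T2H3	cwps	G	0	2031233	2054047	22814
P. laudensis	T2H3	eps	II	0	78886	98046	19160
P. laudensis	T2H4	cwps	F	0	2104194	2117041	12847
P. laudensis	T2H4	cwps	F	1	295725	307559	11834
P. laudensis	T2H4	eps	VII	0	76449	90202	13753
P. raffinolactis	WiKim0068	cwps	H	0	183549	210693	27144
P. raffinolactis	WiKim0068	eps	VIII	0	80195	94639	14444
P. raffinolactis	DSM 20443	cwps	I	0	167655	193821	26166
P. raffinolactis	DSM 20443	eps	IX	0	61407	78976	17569
P. raffinolactis	Lr_19_7	cwps	G	0	231981	253318	21337
P. raffinolactis	Lr_19_7	eps	X	0	102387	125579	23192
P. raffinolactis	Lr_19_5	cwps	E	0	374429	394173	19744
P. raffinolactis	Lr_19_14	cwps	J	0	173936	197235	23299
P. raffinolactis	Lr_19_14	eps	XI	0	1151222	1173701	22479
P. raffinolactis	Lr_18_12S	cwps	K	0	168009	198226	30217
P. raffinolactis	Lr_18_12S	eps	XI	0	1851815	1874084	22269
P. raffinolactis	APC3967	cwps	L	0	152269	181745	29476
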