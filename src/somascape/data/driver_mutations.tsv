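tumour	chrom	pos	gene	detail	loh
709	1	27099037	ARID1A	NM_006015:c.3453_3454insA:p.S1151fs	0
3008	1	27106378	ARID1A	NM_006015:c.A5989G:p.N1997D	1
635	1	237765394	RYR2	NM_001035:c.G4666C:p.E1556Q	0
3034	1	237791238	RYR2	NM_001035:c.C6298T:p.R2100W	0
2010	1	237947202	RYR2	NM_001035:c.G12190A:p.E4064K	0
4070	4	1803568	FGFR3	NM_000142:c.C746G:p.S249C	0
4121	4	1803568	FGFR3	NM_000142:c.C746G:p.S249C	0
615	4	1803568	FGFR3	NM_000142:c.C746G:p.S249C	0
4078	4	1806099	FGFR3	NM_000142:c.A1118G:p.Y373C	1
3010	4	1806099	FGFR3	NM_000142:c.A1118G:p.Y373C	1
4101	4	1806153	FGFR3	NM_000142:c.C1172A:p.A391E	0
4078	4	187522477	FAT1	NM_005245:c.T11586A:p.Y3862X	1
451	4	187542642	FAT1	NM_005245:c.G5098T:p.E1700X	0
3034	6	36652054	CDKN1A	NM_000389:c.176_177insG:p.L59fs	0
745	6	36652071	CDKN1A	NM_000389:c.T193A:p.W65R	1
2010	9	21974695	CDKN2A	NM_000077:c.132_133insA:p.Y44_G45delinsX	1
4062	9	135776983	TSC1	NM_001162427:c.C2342T:p.S781F	1
4062	9	135781212	TSC1	NM_001162427:c.C1600G:p.P534A	1
4062	9	135781386	TSC1	NM_001162427:c.C1426G:p.Q476E	1
3008	9	135781446	TSC1	NM_001162427:c.1365delC:p.P455fs	1
4062	12	49427530	MLL2	NM_003482:c.G10958C:p.G3653A	0
4062	12	49427912	MLL2	NM_003482:c.G10678A:p.D3560N	0
4121	12	49431499	MLL2	NM_003482:c.G9640C:p.E3214Q	0
4121	12	49431871	MLL2	NM_003482:c.G9268C:p.E3090Q	0
4121	12	49431937	MLL2	NM_003482:c.G9202A:p.E3068K	0
4101	12	49434561	MLL2	NM_003482:c.6991delC:p.L2331X	0
4101	12	49438067	MLL2	NM_003482:c.C5104T:p.R1702X	0
451	12	49439934	MLL2	NM_003482:c.4607_4608insA:p.S1536fs	0
451	12	49445797	MLL2	NM_003482:c.1668delG:p.P556fs	0
3008	15	33261489	FMN1	NM_001103184:c.G1744A:p.V582I	0
3034	15	33359823	FMN1	NM_001103184:c.C263T:p.S88L	1
615	16	67183392	B3GNT9	NM_033309:c.C997T:p.H333Y	0
615	16	67183539	B3GNT9	NM_033309:c.C850G:p.P284A	0
745	16	67184036	B3GNT9	NM_033309:c.T353A:p.L118Q	1
3010	17	7577094	TP53	NM_001126115:c.C448T:p.R150W	1
2010	17	7577127	TP53	NM_001126115:c.G415A:p.E139K	1
799	17	7578395	TP53	NM_001126115:c.C139T:p.H47Y	0
799	17	7578475	TP53	NM_001126115:c.C59T:p.P20L	0
615	18	10784798	PIEZO2	NM_022068:c.G2476C:p.D826H	0
4070	18	11066210	PIEZO2	NM_022068:c.C76T:p.R26X
615	X	44820628	KDM6A	NM_021140:c.326_329del:p.109_110del
4070	X	44922729	KDM6A	NM_021140:c.1591_1606del:p.531_536del
3034	X	44941984	KDM6A	NM_021140:c.3234_3235insT:p.P1078fs
4078	X	44942842	KDM6A	NM_021140:c.3422_3423insC:p.S1141fs
799	X	44949105	KDM6A	NM_021140:c.3666_3667insG:p.A1222fs
4101	X	123196821	STAG2	NM_006603:c.1709delC:p.A570fs
451	X	123200065	STAG2	NM_006603:c.2137_2138insA:p.Y713_K714delinsX
3010	X	123202462	STAG2	NM_006603:c.T2314C:p.C772R
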