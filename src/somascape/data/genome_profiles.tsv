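tumour	stage	tumour_pct	esm	gsm	cnv_pct	n_cnvs	clonality
4062	pTa	70	146	34966	14	654	2
4070	pTa	90	137	33861	14	658	1
4078	pTa	80	179				2
4101	pTa	80	154	32608	12	669	1
4121	pTa	70	235	40678	19	729	2
635	pT1	70	920	113970	42	633	2
709	pT1	70	541	110745	39	741	2
745	pT1	80	427	122353	67	888	20
799	pT1	80	272	123701	47	629	13
3010	pT1	90	350	139673	33	812	16
451	pT2	90	385	111643	20	644	5
615	pT2	90	892	108578	31	703	3
2010	pT2	70	482	122547	53	710	29
3008	pT2	80	402	117965	24	557	36
3034	pT2	80	495	99990	69	1233	4
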