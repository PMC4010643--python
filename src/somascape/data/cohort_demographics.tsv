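tumour	age	sex	smoking	grade
4062	69	F	Ex-	G2
4070	74	M	Passive	G2
4078	56	M	Current	G2
4101	81	M	Ex-	G1
4121	71	F	Never	G2
635	85	M	Ex-	G3
709	73	F	Current	G3
745	83	F	Ex-	G3
799	87	M	Ex-	G3
3010	78	F	Ex-	G3
451	78	M	Ex-	G3
615	75	F	Ex-	G2
2010	76	F	Ex-	G3
3008	82	F	Ex-	G3
3034	77	F	Never	G3
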