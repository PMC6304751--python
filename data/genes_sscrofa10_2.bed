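3	73915120	73931838	CYP26B1
5	20494142	20504958	GTSF1
8	144868127	145004045	SCD5
8	145145810	145172579	ENOPH1
9	19211762	19238971	PCF11
9	126641116	126647827	FASLG
9	127044586	127046516	TNFSF4
9	127140870	127151423	TNFSF18
10	61450694	61502941	ITGB1
12	35849614	36000403	TEX14
12	36030881	36043170	SEPT4
12	36070711	36117782	HSF5
12	36120599	36181669	RNF43
16	56921613	56956559	FGF18
16	57021618	57023726	TLX3
16	57477085	57495797	GABRP
17	29095047	29329854	PCSK2
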