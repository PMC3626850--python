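tucr	fold_sk_n_be	fold_lan_5	fold_sh_sy5y	type	orientation	host_gene	ucr_host_correlation	previous_reports	p_value
uc.324	5.57	2.68	9.86	Exon	anti-sense	MPPED2			0.0019
uc.127a	2.02	2.12	1.57	Intergenic	0	0			0.0026
uc.75	1.86	2.66	1.77	Exon	anti-sense	ZEB2			0.0030
uc.345a	2.02	2.37	1.92	Intron	anti-sense	HOXC4			0.0066
uc.409	2.29	2.45	2.33	Intergenic	0	0		FRA<2MB (Calin et al., 2007)	0.0107
uc.109	3.58	2.16	3.52	Intron	anti-sense	LOC375295		HOX cluster (Calin et al., 2007)	0.0123
uc.113a	2.46	2.48	1.33	Intergenic	0	0			0.0134
uc.465a	2.62	1.89	1.63	Intron	anti-sense	POLA1			0.0154
uc.344	1.41	2.86	3.38	Intron	sense	HOXC4	Sig. correlated	FRA<2MB (Calin et al., 2007)	0.0156
uc.359a	5.08	2.35	1.33	Exon	sense	NOVA1	Sig. correlated		0.0194
uc.198a	1.31	2.25	2.76	Intergenic	0	0			0.0204
uc.206	1.14	2.01	2.24	Intergenic	0	0			0.0245
uc.217	1.25	2.39	2.44	Exon	sense	VSTM2A	Sig. correlated		0.0256
uc.451	1.15	3.01	4.67	Intron	anti-sense	TSHZ3			0.0297
uc.341a	1.28	4.54	1.92	Exon	anti-sense	HOXC10		FRA<2MB (Calin et al., 2007)	0.0303
uc.396	1.11	3.77	1.75	Intergenic	0	0		Down-regulated in HCC (Calin et al., 2007)	0.0346
uc.481a	0.38	0.41	0.33	Exon	anti-sense	STAG2			0.0005
uc.195a	0.50	0.38	0.21	Intron	sense	C6orf167	No data available		0.0013
uc.49a	0.48	0.66	0.29	Exon	sense	FAM98A	No data available	Inferred role in differentiation for UCR49 (Mestdagh et al., 2010)	0.0082
uc.449	0.42	0.49	0.64	Intron	sense	ZNF536	No data available		0.0086
uc.203	0.18	0.47	0.59	Exon	sense	QKI	Sig. correlated	LOH (Calin et al., 2007)	0.0097
uc.48	0.31	0.75	0.31	Exon	anti-sense	PUM2			0.0109
uc.419a	0.35	0.78	0.36	Exon	sense	SFRS1	Not Correlated	FRA<2MB, HPV16<2.5MB (Calin et al., 2007)	0.0125
uc.50a	0.35	0.68	0.27	Intron	sense	SFRS7	Sig. correlated		0.0131
uc.300a	0.38	0.51	0.79	Intron	anti-sense	PAX2		LOH, HOX gene, Up-regulated in CRC (Calin et al., 2007)	0.0135
uc.284	0.81	0.09	0.14	Intergenic	0	0			0.0138
uc.48a	0.37	0.59	0.48	Exon	sense	PUM2	No data available		0.0160
uc.243	0.59	0.27	0.67	Intron	sense	ZFHX4	Not correlated	AMPLIF (Calin et al., 2007)	0.0176
uc.163	0.59	0.41	0.51	Intergenic	0	0			0.0179
uc.388	0.28	0.75	0.47	Intron	sense	TCF12	No data available	Up-regulated in CRC (Calin et al., 2007) Down-regulated in CRC (Sana et al., 2012)	0.0202
uc.97	0.55	0.65	0.28	Intron	sense	HAT1	Not correlated	HOX gene (Calin et al., 2007)	0.0307
uc.82a	0.40	0.37	0.99	Intergenic	0	0			0.0499
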