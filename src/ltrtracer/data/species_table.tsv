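species	abbreviation	life_cycle	accession	read_pairs	c2_pg	c2_se	genome_coverage	repetitive_fraction_pct	repetitive_fraction_se
H. praecox	PRA	annual	PI 435847	10314126	6.94	0.10	0.59	68.17	0.18
H. annuus	ANN	annual	PI 468607	12060743	7.36	0.12	0.67	68.97	0.21
H. cusickii	CUS	perennial	PI 649959	11981577	9.32	0.24	0.51	74.58	0.18
H. divaricatus	DIV	perennial	PI 503212	6752840	9.41	0.08	0.29	69.55	0.29
H. anomalus	ANO	annual	PI 468642	12228849	11.82	0.37	0.41	75.26	0.19
H. heterophyllus	HET	perennial	PI 664732	11753278	11.82	0.29	0.40	71.42	0.20
H. angustifolius	ANG	perennial	ANG-MCU	6837151	12.91	0.32	0.21	73.38	0.33
H. agrestis	AGR	annual	PI 468416	16909589	24.23	0.84	0.28	82.12	0.15
P. tenuifolius	PHO	perennial	PHO-LA	10971465	13.94	0.71	0.31	74.08	0.16
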