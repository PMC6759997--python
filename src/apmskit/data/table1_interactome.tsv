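fraction	gene_symbol	accession	mw_kDa	protein_name	nsaf_bait_pct	nsaf_control_pct
TPE	YWHAE	P62258	29.17	14-3-3 protein epsilon	2.64	0.21
TPE	YWHAB	P31946	28.082	14-3-3 protein beta/alpha	1.14	0.00
TPE	SLC25A5	P05141	32.852	ADP/ATP translocase 2	1.08	0.06
TPE	YWHAH	Q04917	28.219	14-3-3 protein eta	0.97	0.00
TPE	RPS3	P23396	26.688	40S ribosomal protein S3	0.81	0.26
TPE	YWHAG	P61981	28.3	14-3-3 protein gamma	0.81	0.00
TPE	TUBB6	Q9BUF5	49.857	Tubulin beta-6 chain	0.76	0.00
TPE	SLC25A11	Q02978	34.062	Mitochondrial 2-oxoglutarate/malate carrier protein	0.66	0.08
TPE	NTPCR	Q9BSD7	20.713	Cancer-related nucleoside-triphosphatase	0.57	0.00
TPE	RPS15A	P62244	14.84	40S ribosomal protein S15a	0.53	0.00
TPE	SLC25A13	Q9UJS0	74.176	Calcium-binding mitochondrial carrier protein Aralar2	0.47	0.00
TPE	RPL9	P32969	21.863	60S ribosomal protein L9	0.46	0.00
TPE	ARF4	P18085	20.511	ADP-ribosylation factor 4	0.46	0.00
TPE	CCT4	P50991	57.924	T-complex protein 1 subunit delta	0.43	0.12
TPE	PGAM5	Q96HS1	32.004	Serine/threonine-protein phosphatase PGAM5, mitochondrial	0.40	0.06
TPE	MCM7	P33993	81.308	DNA replication licensing factor MCM7	0.39	0.00
TPE	PCBP2	Q15366	38.58	Poly(rC)-binding protein 2	0.39	0.00
TPE	PCBP1	Q15365	37.498	Poly(rC)-binding protein 1	0.37	0.00
TPE	TIMM50	Q3ZCQ8	39.646	Mitochondrial import inner membrane translocase subunit TIM50	0.37	0.00
TPE	RPL23	P62829	14.865	60S ribosomal protein L23	0.34	0.00
TPE	PPP3CA	Q08209	58.688	Serine/threonine-protein phosphatase 2B catalytic subunit alpha isoform	0.34	0.00
TPE	PCNA	P12004	28.769	Proliferating cell nuclear antigen	0.33	0.00
NE	VIM	P08670	53.65	Vimentin	1.11	0.19
NE	PHB2	Q99623	33.296	Prohibitin-2	1.03	0.08
NE	DDX3X	O00571	73.243	ATP-dependent RNA helicase DDX3X	0.81	0.11
NE	PGAM5	Q96HS1	32.004	Serine/threonine-protein phosphatase PGAM5, mitochondrial	0.81	0.00
NE	TUBA1C	Q9BQE3	49.895	Tubulin alpha-1C chain	0.73	0.00
NE	RPS3	P23396	26.688	40S ribosomal protein S3	0.64	0.00
NE	SMC1A	Q14683	143.23	Structural maintenance of chromosomes protein 1A	0.60	0.02
NE	DDX21	Q9NR30	87.344	Nucleolar RNA helicase 2	0.58	0.00
NE	ATAD3A	Q9NVI7	71.369	ATPase family AAA domain-containing protein 3A	0.57	0.04
NE	SMC3	Q9UQE7	141.54	Structural maintenance of chromosomes protein 3	0.49	0.02
NE	PRKDC	P78527	469.089	DNA-dependent protein kinase catalytic subunit	0.46	0.04
NE	NXF1	Q9UBU9	70.182	Nuclear RNA export factor 1	0.40	0.04
NE	RUVBL1	Q9Y265	50.22	RuvB-like 1	0.36	0.00
NE	RBM14	Q96PK6	69.492	RNA-binding protein 14	0.32	0.03
NE	AIFM1	O95831	66.901	Apoptosis-inducing factor 1, mitochondrial	0.30	0.00
NE	ELAVL1	Q15717	36.092	ELAV-like protein 1	0.29	0.00
NE	IRS4	O14654	133.768	Insulin receptor substrate 4	0.24	0.00
NE	WDR6	Q9NNW5	121.725	WD repeat-containing protein 6	0.22	0.00
NE	NUP205	Q92621	227.922	Nuclear pore complex protein Nup205	0.19	0.01
NE	NUP160	Q12769	162.121	Nuclear pore complex protein Nup160	0.16	0.00
NE	PDCD11	Q14690	208.701	Protein RRP5 homolog	0.09	0.00
NE	RANBP2	P49792	358.199	E3 SUMO-protein ligase RanBP2	0.09	0.00
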