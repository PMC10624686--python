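chrom	ref	alt	annotation	impact	gene	hgvs_c	hgvs_c_alias	group	cosmic_raw	cosmic_id	votes	wes_total_reads	wes_variant_reads	wes_vaf_percent	sm_mean	sm_sem	dm_mean	dm_sem	cl_mean	cl_sem	pbl_mean	pbl_sem
5	T	A	stop_gained	HIGH	APC	c.4128T>A		CRC	COSM1886155			63	4	6.35	0.09	0.03	0.08	0.05	5.61	0.36	0.18	0.07
5	C	T	stop_gained	HIGH	APC	c.2626C>T		CRC	COSM188525			142	61	42.96	0.12	0.05	0.15	0.01	34.70	0.73	0.08	0.03
9	G	A	missense	MODERATE	LAMC3	c.1241G>A		CRC_surrounding	COSM12563083	COSM1256308	3	152	11	7.24	2.51	0.14	0.51	0.09	0.14	0.02	0.07	0.05
14	G	A	missense	MODERATE	NRXN3	c.1421G>A	c.308G>A	CRC_surrounding	COSM49732795	COSM4973279	5	46	5	10.87	5.85	0.45	4.02	1.05	0.15	0.05	0.13	0.05
19	C	T	missense	MODERATE	ASNA1	c.193C>T		CRC_surrounding	COSM16807085			44	3	6.82	3.82	0.19	0.12	0.07	0.11	0.03	0.32	0.11
9	G	A	missense	MODERATE	NTRK2	c.220G>A		AAD_surrounding	COSM174142958			148	4	2.70	0.18	0.03	0.21	0.09	0.21	0.09	0.39	0.13
8	C	T	stop_gained	MODERATE	FABP4	c.109G>A	c.105G>A	AAD_surrounding	COSM2726544			146	4	2.74	0.02	0.01	0.10	0.06	0.06	0.06	0.09	0.03
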