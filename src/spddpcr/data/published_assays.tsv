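gene	hgvs_c	hgvs_c_alias	chrom	ref	alt	direction	strategy	anchor	bridge	foot	complementary_primer	standard_primer	amplicon	lod_percent	lod_mean	lod_sd	lod_genomic_percent	lod_genomic_mean	lod_genomic_sd
APC	c.4128T>A		5	T	A	forward	21–7/8–5:1:1	GTGCTCAGACACCCAAAAGTC	ATATATA	CACTAAG	ATCTGCTAAACATGAGTGGGGTC	GTGCTCAGACACCCAAAAGTC	GTGCTCAGACACCCAAAAGTCCACCTGAACACTA(T/A)GTTCAGGAGACCCCACTCATGTTTAGCAGAT	0.22	0.14	0.03
APC	c.2626C>T		5	C	T	reverse	18–8/7–4:1:1	GGCTGCAGTGGTGGAGAT	ATATATAT	CCTCAC	GCAACAGAAAATCCAGGAACTTCT	GGCTGCAGTGGTGGAGAT	GCAACAGAAAATCCAGGAACTTCTTCAAAG(C/T)GAGGTTTGCAGATCTCCACCACTGCAGCC	0.18	0.08	0.03
LAMC3	c.1241G>A		9	G	A	reverse	19–8/6–4:1:1	CACTGAGCGAGTGGAACCC	ATATATAT	ACAGTG	CGGTGACTGGCTGGAAGT	CCTCACTGAGCGAGTGGAACCC	CCACGGTGACTGGCTGGAAGTGTGACC(G/A)CTGTCTGCCCGGGTTCCACTCGCTCAGTGAGG	0.14	0.05	0.03
NRXN3	c.1421G>A	c.308G>A	14	G	A	forward	21–8/5–4:1:1	AACGTATGGGCTCCATCTCCT	ATATATAT	TTCCAC	TCAGGCCATTGGGCTCTGT	AACGTATGGGCTCCATCTCCT	AACGTATGGGCTCCATCTCCTTTGACTTCC(G/A)CACCACAGAGCCCAATGGCCTGA	0.19	0.08	0.04
ASNA1	c.193C>T		19	C	T	reverse	22–10/5–4:1:1	GGGTCTGTGGAGATGATCAGAA	ATATATAT	TCACAC	CTGGCAGTCCAGCTCTCC	GGGTCTGTGGAGATGATCAGAA	CTGGCAGTCCAGCTCTCCAAGGGG(C/T)GTGAGAGTGTTCTGATCATCTCCACAGACCC	0.32	0.15	0.05
NTRK2	c.220G>A		9	G	A	reverse	28–6/4–5:1:1	CATCTTCGTTGATGATTTCTAACCTTT	TATATAT	GTTTGTG	CACTCTCTGCTTTGTTACAGTTTCA	TCTTCGTTGATGATTTCTAACCTTT	CACTCTCTGCTTTGTTACAGTTTCATC(G/A)CAAACCAGAAAAGGTTAGAAATCATCAACGAAGA	0.11	0.05	0.02	0.40	0.19	0.07
FABP4	c.109G>A	c.105G>A	8	C	T	reverse	20–6/5–4:1:1	GCTTTGCCACCAGGAAAGTG	TATATAT	CATGAC	TCACACTGATGATCATGTTAGGTTTG	TTTGCCACCAGGAAAGTG	CACTGATGATCATGTTAGGTTTGG(C/T)CATGCCAGCCACTTTCCTGGTGGCAAAGC	0.10	0.03	0.03
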