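Module	Gene	Probes	Chr	Probe_Start	Probe_End	beta	SEM	P Value
M19	SDHB	ILMN_1667257	1	17476541	17476590	-0.053	0.0094	2.66e-8
M19	NDUFB3	ILMN_2119945	2	201943702	201944702	-0.034	0.0120	5.24e-3
M19	COX17	ILMN_2187718	3	119396160	119396209	-0.031	0.0139	0.0286
M19	ATP5I	ILMN_1772506	4	678058	678107	-0.020	0.0090	0.0244
M19	UQCRQ	ILMN_1666471	5	132174747	132174796	-0.045	0.0108	3.55e-5
M19	COX7A2	ILMN_1701293	6	75950943	75950943	-0.028	0.0104	7.53e-3
M19	ATP5J2	ILMN_2307883	7	99217929	99217978	-0.035	0.0112	1.58e-3
M19	NDUFB2	ILMN_2117330	7	140402713	140402762	-0.039	0.0122	1.44e-3
M19	COX6C	ILMN_1654151	8	100904152	100904201	-0.024	0.0083	4.07e-3
M19	COX8A	ILMN_1809495	11	63742263	63743263	-0.042	0.0108	1.16e-4
M19	NDUFA9	ILMN_1760741	12	4796151	4796200	-0.049	0.0124	1.04e-4
M19	ATP5G2	ILMN_1660577	12	54063071	54063120	-0.006	0.0133	0.675
M19	COX6A1	ILMN_1783636	12	120876242	120876291	-0.018	0.0118	0.119
M19	NDUFA11	ILMN_2175712	19	5945952	5946001	-0.028	0.0115	0.0142
M19	NDUFB7	ILMN_1813604	19	14816068	14817068	-0.020	0.0114	0.0764
M19	COX6B1	ILMN_2154671	19	36139232	36139281	-0.028	0.0094	0.0355
M19	ATP5J	ILMN_2348093	21	28180168	28180217	-0.041	0.0109	1.63e-4
M19	NDUFA1	ILMN_1784286	X	119005887	119005936	-0.034	0.0099	6.42e-4
M15	ATP5F1	ILMN_1721989	1	112003559	112003608	-0.022	0.0093	0.0195
M15	PPA2	ILMN_1687785	4	106292029	106293029	-0.023	0.0148	0.123
M15	NDUFC1	ILMN_1733603	4	140216254	140217254	0.007	0.0126	0.559
M15	NDUFA4	ILMN_1751258	7	11006668	11006717	-0.007	0.0123	0.559
M15	ATP5C1	ILMN_1701269	10	7801069	7801118	-0.032	0.0133	0.0157
M15	SDHD	ILMN_1698487	11	111966144	111966193	-0.016	0.0145	0.262
M15	ATP5L	ILMN_2079285	11	118280301	118280350	-0.013	0.0160	0.426
M15	NDUFAB1	ILMN_2179018	16	23684934	23684983	-0.026	0.0138	0.0561
M15	ATP5H	ILMN_1666372	17	75524607	75524656	-0.034	0.0097	5.44e-4
M15	NDUFV2	ILMN_2086417	18	9126871	9127871	-0.022	0.0125	0.0754
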