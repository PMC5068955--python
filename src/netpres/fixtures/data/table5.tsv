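Module	Gene	Probes	Chr	Probe_Start	Probe_End	beta	SEM	P Value
M19	SDHB	ILMN_1667257	1	17476541	17476590	0.027	0.0116	0.021
M19	NDUFB3	ILMN_2119945	2	201943702	201944702	0.072	0.0143	5.22e-7
M19	COX17	ILMN_2187718	3	119396160	119396209	0.064	0.0167	1.36e-4
M19	ATP5I	ILMN_1772506	4	678058	678107	0.042	0.0107	9.34e-5
M19	UQCRQ	ILMN_1666471	5	132174747	132174796	0.035	0.0131	8.31e-3
M19	COX7A2	ILMN_1701293	6	75950943	75950943	0.055	0.0123	8.29e-6
M19	ATP5J2	ILMN_2307883	7	99217929	99217978	0.061	0.0133	5.13e-6
M19	NDUFB2	ILMN_2117330	7	140402713	140402762	0.035	0.0147	9.62e-3
M19	COX6C	ILMN_1654151	8	100904152	100904201	0.055	0.0098	4.27e-8
M19	COX8A	ILMN_1809495	11	63742263	63743263	0.056	0.0128	1.74e-5
M19	NDUFA9	ILMN_1760741	12	4796151	4796200	0.058	0.0152	1.08e-4
M19	ATP5G2	ILMN_1660577	12	54063071	54063120	0.024	0.0159	0.128
M19	COX6A1	ILMN_1783636	12	120876242	120876291	0.071	0.0139	3.81e-7
M19	NDUFA11	ILMN_2175712	19	5945952	5946001	0.027	0.0139	0.055
M19	NDUFB7	ILMN_1813604	19	14816068	14817068	0.026	0.0137	0.055
M19	COX6B1	ILMN_2154671	19	36139232	36139281	0.022	0.0114	0.053
M19	ATP5J	ILMN_2348093	21	28180168	28180217	0.023	0.0132	0.086
M19	NDUFA1	ILMN_1784286	X	119005887	119005936	0.031	0.0119	0.010
M15	ATP5F1	ILMN_1721989	1	112003559	112003608	0.033	0.0112	3.32e-3
M15	PPA2	ILMN_1687785	4	106292029	106293029	0.000	0.0178	0.967
M15	NDUFC1	ILMN_1733603	4	140216254	140217254	0.026	0.0152	0.085
M15	NDUFA4	ILMN_1751258	7	11006668	11006717	0.051	0.0146	4.65e-4
M15	ATP5C1	ILMN_1701269	10	7801069	7801118	0.028	0.0160	0.079
M15	SDHD	ILMN_1698487	11	111966144	111966193	0.027	0.0174	0.122
M15	ATP5L	ILMN_2079285	11	118280301	118280350	0.009	0.0192	0.655
M15	NDUFAB1	ILMN_2179018	16	23684934	23684983	0.052	0.0165	1.86e-3
M15	ATP5H	ILMN_1666372	17	75524607	75524656	0.020	0.0118	0.083
M15	NDUFV2	ILMN_2086417	18	9126871	9127871	0.044	0.0150	3.52e-3
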