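Module	Gene	Probes	Chr	Probe_Start	Probe_End	beta	SEM	P Value
M19	SDHB	ILMN_1667257	1	17476541	17476590	0.024	0.0135	0.080
M19	NDUFB3	ILMN_2119945	2	201943702	201944702	0.045	0.0168	6.82e-3
M19	COX17	ILMN_2187718	3	119396160	119396209	0.000	0.0195	0.982
M19	ATP5I	ILMN_1772506	4	678058	678107	0.0144	0.0125	0.250
M19	UQCRQ	ILMN_1666471	5	132174747	132174796	0.013	0.0152	0.389
M19	COX7A2	ILMN_1701293	6	75950943	75951943	0.019	0.0145	0.182
M19	ATP5J2	ILMN_2307883	7	99217929	99217978	0.028	0.0156	0.075
M19	NDUFB2	ILMN_2117330	7	140402713	140402762	-0.008	0.0172	0.635
M19	COX6C	ILMN_1654151	8	100904152	100904201	0.006	0.0116	0.611
M19	COX8A	ILMN_1809495	11	63742263	63743263	0.020	0.0152	0.183
M19	NDUFA9	ILMN_1760741	12	4796151	4796200	0.040	0.0175	0.021
M19	ATP5G2	ILMN_1660577	12	54063071	54063120	-0.027	0.0185	0.137
M19	COX6A1	ILMN_1783636	12	120876242	120876291	0.024	0.0164	0.146
M19	NDUFA11	ILMN_2175712	19	5945952	5946001	-0.018	0.0162	0.259
M19	NDUFB7	ILMN_1813604	19	14816068	14817068	-0.002	0.0159	0.876
M19	COX6B1	ILMN_2154671	19	36139232	36139281	-0.019	0.0132	0.150
M19	ATP5J	ILMN_2348093	21	28180168	28180217	-0.010	0.0154	0.509
M19	NDUFA1	ILMN_1784286	X	119005887	119005936	0.017	0.0139	0.232
M15	ATP5F1	ILMN_1721989	1	112003559	112003608	0.033	0.0130	0.0110
M15	PPA2	ILMN_1687785	4	106292029	106293029	0.046	0.0205	0.0256
M15	NDUFC1	ILMN_1733603	4	140216254	140217254	0.050	0.0175	4.70e-3
M15	NDUFA4	ILMN_1751258	7	11006668	11006717	0.033	0.0171	0.0522
M15	ATP5C1	ILMN_1701269	10	7801069	7801118	0.074	0.0183	5.64e-5
M15	SDHD	ILMN_1698487	11	111966144	111966193	0.049	0.0201	0.015
M15	ATP5L	ILMN_2079285	11	118280301	118280350	0.049	0.022	0.029
M15	NDUFAB1	ILMN_2179018	16	23684934	23684983	0.091	0.0190	2.12e-6
M15	ATP5H	ILMN_1666372	17	75524607	75524656	0.029	0.0136	0.031
M15	NDUFV2	ILMN_2086417	18	9126871	9127871	0.104	0.0170	1.89e-9
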