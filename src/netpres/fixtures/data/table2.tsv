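Preserved Module	n_c	Pathway	Enrichment Score	FDR	No. of Genes	Genes
M19	131	Oxidative phosphorylation	8.92	3.28e-11	18	NDUFB3, ATP5J2, COX7A2, NDUFB7, NDUFA9, COX8A, ATP5G2, UQCRQ, NDUFA1, COX6C, NDUFB2, NDUFA11, SDHB, COX6B1, COX6A1, ATP5I, COX17, ATP5J
M19	131	Huntington disease		8.85e-8	17	NDUFB3, CLTA, COX7A2, POLR2L, NDUFB7, NDUFA9, COX8A, POLR2I, ATP5G2, UQCRQ, NDUFA1, COX6C, NDUFB2, SDHB, COX6B1, COX6A1, ATP5J
M19	131	Diabetes pathway		3.62e-7	20	NDUFB3, ATP5J2, NDUFB11, NDUFB7, NDUFA9, COX8A, NDUFA13, UQCRQ, NDUFA1, NDUFA12, COX6C, NDUFB2, NDUFA11, SDHB, IDH3G, COX6B1, DAD1, COX6A1, ATP5I, ATP5J
M19	131	Parkinson disease		1.31e-6	14	NDUFB3, COX7A2, NDUFB7, NDUFA9, COX8A, ATP5G2, NDUFA1, UQCRQ, NDUFB2, COX6C, SDHB, COX6B1, COX6A1, ATP5J
M19	131	Alzheimer disease		2.57e-5	14	NDUFB3, COX7A2, NDUFB7, NDUFA9, COX8A, ATP5G2, NDUFA1, UQCRQ, NDUFB2, COX6C, SDHB, COX6B1, COX6A1, ATP5J
M15	137	Oxidative phosphorylation	4.17	0.003	10	NDUFA4, NDUFV2, SDHD, NDUFAB1, ATP5F1, ATP5C1, ATP5L, NDUFC1, ATP5H, PPA2
M15	137	Parkinson disease		0.025	9	NDUFA4, CASP9, NDUFV2, SDHD, NDUFAB1, ATP5F1, ATP5C1, NDUFC1, ATP5H
M15	137	Huntington disease		0.044	10	NDUFA4, CASP9, NDUFV2, SDHD, NDUFAB1, ATP5F1, ATP5C1, NDUFC1, ATP5H, TBPL1
M15	137	Alzheimer disease		0.14	9	NDUFA4, CASP9, NDUFV2, SDHD, NDUFAB1, ATP5F1, ATP5C1, NDUFC1, ATP5H
M15	137	Diabetes pathway		0.30	13	NDUFA4, SEC11C, NDUFAB1, ATP5F1, NDUFC1, DLD, SDHD, NDUFV2, ATP5C1, ATP5L, ATP5H, SRP9, FH
M15	137	Proteasome	3.72	1.37e-3	8	UBE2N, PSMD14, UBE2D2, PSMD12, PSMC2, UCHL5, PSMD6, PSMD7
M21	96	Ribosome	26.70	8.85e-27	22	RPL18, RPSA, RPL17, RPL35, RPS9, RPL27, RPL38, RPS6, RPS5, RPS25, RPS19, RPL31, RPL22, RPL3, RPL5, RPS10, RPL11, RPL4, RPS20, RPL10A, UBA52, RPS24
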