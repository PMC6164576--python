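module	mirna	gene	context_percentile	r_pair	fdr_pair	trait	r_mirna_trait	fdr_mirna_trait	r_gene_trait	fdr_gene_trait
Blue	bta-let-7a-5p	STX3	97	-0.428	0.022	Protein percentage	0.484	0.010	-0.438	0.023
Blue	bta-let-7b	APBB3	98	-0.394	0.037	Protein yield	-0.400	0.041	0.620	<0.001
Blue	bta-let-7b	C14orf28	97	-0.485	0.008	Milk yield	-0.509	0.006	0.424	0.029
Blue	bta-let-7b	MXD1	97	-0.457	0.014	Protein yield	-0.400	0.041	0.446	0.020
Blue	bta-let-7b	PPP1R15B	96	-0.420	0.025	Protein yield	-0.400	0.041	0.609	0.001
Blue	bta-let-7b	QARS	98	-0.386	0.041	Milk yield	-0.509	0.006	0.491	0.009
Blue	bta-let-7b	SLC20A1	96	-0.391	0.039	Milk yield	-0.509	0.006	0.502	0.007
Blue	bta-let-7b	STX3	97	-0.464	0.012	Protein yield	-0.400	0.041	0.531	0.004
Blue	bta-let-7b	THTPA	98	-0.431	0.021	Protein yield	-0.400	0.041	0.409	0.036
Blue	bta-let-7b	TP53	97	-0.413	0.028	Protein yield	-0.400	0.041	0.459	0.016
Blue	bta-miR-183	CTDSP1	98	-0.433	0.020	Protein yield	-0.452	0.018	0.443	0.021
Blue	bta-miR-183	DGCR2	99	-0.516	0.005	Protein yield	-0.452	0.018	0.442	0.021
Blue	bta-miR-183	HLTF	98	-0.428	0.022	Protein yield	-0.452	0.018	0.502	0.007
Blue	bta-miR-183	HNRNPA1	96	-0.479	0.009	Milk yield	-0.599	0.001	0.414	0.034
Blue	bta-miR-183	ICA1	99	-0.443	0.017	Protein yield	-0.452	0.018	0.548	0.003
Blue	bta-miR-183	ILF2	96	-0.373	0.050	C17:0	0.414	0.033	-0.400	0.041
Blue	bta-miR-183	MAFF	97	-0.427	0.022	Milk yield	-0.599	0.001	0.467	0.014
Blue	bta-miR-183	MGME1	98	-0.456	0.014	Milk yield	-0.599	0.001	0.399	0.042
Blue	bta-miR-183	MTA1	99	-0.475	0.010	Protein yield	-0.452	0.018	0.415	0.033
Blue	bta-miR-183	PPP2R5C	95	-0.446	0.017	Milk yield	-0.599	0.001	0.433	0.025
Blue	bta-miR-183	RHBDD2	95	-0.538	0.003	Protein percentage	0.547	0.003	-0.411	0.035
Blue	bta-miR-183	RHPN2	99	-0.407	0.031	Milk yield	-0.599	0.001	0.433	0.025
Blue	bta-miR-183	SESN1	97	-0.375	0.048	Protein yield	-0.452	0.018	0.396	0.043
Blue	bta-miR-183	SFT2D1	97	-0.500	0.006	C17:0	0.414	0.033	-0.425	0.028
Blue	bta-miR-183	SPRY2	99	-0.418	0.026	Protein yield	-0.452	0.018	0.488	0.009
Blue	bta-miR-183	SRSF2	98	-0.473	0.010	Protein yield	-0.452	0.018	0.617	0.001
Blue	bta-miR-183	UTP6	96	-0.432	0.021	protein yield	-0.452	0.018	0.545	0.003
Blue	bta-miR-183	ZFAND5	99	-0.427	0.022	protein yield	-0.452	0.018	0.430	0.026
Blue	bta-miR-2284b	ACVR1	96	-0.419	0.025	Milk yield	-0.442	0.021	0.416	0.032
Blue	bta-miR-2284b	ARL15	97	-0.443	0.017	protein yield	-0.429	0.026	0.427	0.027
Blue	bta-miR-2284b	CCNT2	96	-0.398	0.035	protein yield	-0.429	0.026	0.439	0.023
Blue	bta-miR-2284b	CLIC2	99	-0.416	0.027	protein yield	-0.429	0.026	0.610	0.001
Blue	bta-miR-2284b	ERG	95	-0.448	0.016	protein yield	-0.429	0.026	0.393	0.045
Blue	bta-miR-2284b	FAM114A1	96	-0.425	0.023	Milk yield	-0.442	0.021	0.459	0.016
Blue	bta-miR-2284b	FAM8A1	95	-0.386	0.042	protein yield	-0.429	0.026	0.414	0.033
Blue	bta-miR-2284b	FAR1	95	-0.387	0.041	Milk yield	-0.442	0.021	0.399	0.042
Blue	bta-miR-2284b	IVNS1ABP	95	-0.404	0.032	protein yield	-0.429	0.026	0.509	0.006
Blue	bta-miR-2284b	LBR	96	-0.510	0.005	protein yield	-0.429	0.026	0.462	0.015
Blue	bta-miR-2284b	LIMA1	97	-0.446	0.017	protein yield	-0.429	0.026	0.403	0.039
Blue	bta-miR-2284b	NRROS	96	-0.406	0.031	Milk yield	-0.442	0.021	0.480	0.011
Blue	bta-miR-2284b	POLR2A	99	-0.415	0.027	protein yield	-0.429	0.026	0.667	0.000
Blue	bta-miR-2284b	RRN3	96	-0.377	0.047	protein yield	-0.429	0.026	0.501	0.007
Blue	bta-miR-2284b	SETD2	97	-0.399	0.035	protein yield	-0.429	0.026	0.438	0.023
Blue	bta-miR-2284b	SLC38A2	95	-0.417	0.026	Milk yield	-0.442	0.021	0.526	0.004
Blue	bta-miR-2284b	THAP2	96	-0.385	0.042	protein yield	-0.429	0.026	0.445	0.020
Blue	bta-miR-2284b	UBE4A	96	-0.414	0.027	protein yield	-0.429	0.026	0.490	0.009
Blue	bta-miR-2284b	ZDHHC17	95	-0.384	0.043	protein yield	-0.429	0.026	0.426	0.028
Blue	bta-miR-2284b	ZNF175	97	-0.407	0.031	Milk yield	-0.442	0.021	0.433	0.025
Blue	bta-miR-23b-3p	RBM4B	95	-0.463	0.012	Milk yield	-0.390	0.047	0.549	0.003
Blue	bta-miR-30d	CAMK2D	95	-0.384	0.042	protein percentage	0.459	0.016	-0.433	0.025
Blue	bta-miR-409a	ALG13	99	-0.490	0.008	Milk yield	-0.553	0.002	0.462	0.015
Blue	bta-miR-409a	GALNT5	96	-0.482	0.009	Protein percentage	0.641	0.000	-0.616	0.001
Blue	bta-miR-409a	RPL11	98	-0.484	0.009	Fat percentage	0.387	0.049	-0.447	0.020
Blue	bta-miR-409a	TMEM159	99	-0.410	0.029	Fat percentage	0.387	0.049	-0.396	0.044
Blue	bta-miR-409a	TRA2B	97	-0.382	0.044	Milk yield	-0.553	0.002	0.598	0.001
Blue	bta-miR-6522	FAM107B	95	-0.384	0.043	Milk yield	-0.441	0.022	0.554	0.002
Blue	bta-miR-6522	ZNF623	95	-0.376	0.048	Milk yield	-0.441	0.022	0.550	0.003
Blue	bta-miR-96	CHST1	98	-0.373	0.050	Milk yield	-0.429	0.026	0.485	0.010
Blue	bta-miR-96	EIF5	96	-0.416	0.027	Milk yield	-0.429	0.026	0.494	0.009
Blue	bta-miR-96	FARP1	97	-0.466	0.012	Milk yield	-0.429	0.026	0.599	0.001
Blue	bta-miR-96	GRHL2	95	-0.398	0.035	Milk yield	-0.429	0.026	0.481	0.011
Blue	bta-miR-96	LONP2	97	-0.439	0.019	Fat percentage	0.613	0.001	-0.415	0.033
Blue	bta-miR-96	PRKAR1A	97	-0.375	0.049	Milk yield	-0.429	0.026	0.442	0.022
Blue	bta-miR-96	SPIN1	95	-0.392	0.038	Milk yield	-0.429	0.026	0.533	0.004
Blue	bta-miR-96	SPROT	97	-0.410	0.029	Milk yield	-0.429	0.026	0.535	0.004
Blue	bta-miR-96	TP53	95	-0.440	0.018	Milk yield	-0.429	0.026	0.427	0.027
Blue	bta-miR-96	TRIB3	97	-0.397	0.035	Fat percentage	0.613	0.001	-0.550	0.003
Blue	bta-miR-96	ZCCHC3	99	-0.453	0.015	Milk yield	-0.429	0.026	0.567	0.002
Brown	bta-miR-484	CPPED1	95	-0.413	0.028	C22:6n3	-0.402	0.040	0.600	0.001
Brown	bta-miR-484	DOLPP1	96	-0.393	0.037	C16:0	0.394	0.045	-0.396	0.043
Brown	bta-miR-484	EIF1AD	95	-0.470	0.011	Fat percentage	0.421	0.030	-0.432	0.025
Brown	bta-miR-484	LY6E	97	-0.420	0.025	C16:0	0.394	0.045	-0.394	0.045
Brown	bta-miR-484	NUDT16	96	-0.390	0.039	Fat percentage	0.421	0.030	-0.456	0.017
Brown	bta-miR-484	QDPR	99	-0.391	0.039	C16:0	0.394	0.045	-0.596	0.001
Turquoise	bta-miR-130a	SBSPON	96	-0.529	0.004	Protein percentage	-0.486	0.010	0.626	<0.001
Turquoise	bta-miR-455-5p	HPGD	99	-0.384	0.043	Protein yield	0.491	0.009	-0.492	0.009
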