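acronym	name	unit	control_mean	control_se	control_min	control_max	linseed_mean	linseed_se	linseed_min	linseed_max	safflower_mean	safflower_se	safflower_min	safflower_max
PROT_Y	Protein yield	kg	1.2	0.06	0.99	1.52	1.24	0.06	0.92	1.53	1.17	0.06	0.89	1.47
FAT_Y	Fat yield	kg	1.31	0.08	1.12	1.74	1.07	0.11	0.61	1.98	0.97	0.07	0.67	1.35
Milk	Milk yield	kg	36.94	2.13	29.24	52.24	38.14	2.42	26.44	53.56	36.64	2.86	26.16	53.34
PRT	Protein percentage	%	3.3	0.1	2.9	3.65	3.31	0.11	2.81	4.17	3.27	0.1	2.74	3.85
LAC	Lactose percentage	%	4.7	0.05	4.47	4.88	4.74	0.05	4.43	4.94	4.65	0.04	4.42	4.84
FAT	Fat percentage	%	3.6	0.12	3.07	4.19	2.8	0.19	1.87	3.7	2.77	0.24	1.42	3.99
TAG	Triacylglyceride	nmol/L	0.05	0	0.02	0.07	0.08	0.01	0.04	0.11	0.08	0.01	0.05	0.12
NEFA	Nonesterified fatty acids	nmol/L	103.86	23.55	48.66	312.99	156.48	13.29	92.75	248.53	154.47	14.72	101.13	276.18
C4:0	Butyric acid	mg/100g of fat	2.81	0.35	1.51	4.95	0.64	0.1	0.06	0.95	0.74	0.08	0.03	0.94
C6:0	Caproic acid	mg/100g of fat	2.39	0.18	1.31	3.58	0.97	0.15	0.28	1.51	1.24	0.16	0.52	2.26
C8:0	Caprylic acid	mg/100g of fat	1.18	0.07	1.05	1.66	0.72	0.06	0.5	0.94	0.76	0.05	0.51	1.04
C12:0	Lauric acid	mg/100g of fat	2.77	0.3	1.01	4.68	1.5	0.24	0.56	3.03	1.44	0.21	0.5	2.93
C14:0	Myristic acid	mg/100g of fat	11.43	0.27	10.22	12.7	7.95	0.41	5.47	9.28	6.96	0.51	5.01	9.86
C15:0	Pentadecylic acid	mg/100g of fat	1.44	0.07	1.13	1.86	0.98	0.07	0.68	1.4	0.99	0.05	0.8	1.4
C16:0	Palmitic acid	mg/100g of fat	26.79	0.28	25.46	28.55	21.17	1.2	16.64	28.7	21.94	0.98	17.22	26.7
C17:0	Margaric acid	mg/100g of fat	0.83	0.1	0.44	1.73	0.93	0.12	0.36	1.49	0.73	0.1	0.16	1.29
C18:0	Stearic acid	mg/100g of fat	11.13	0.54	8.02	13.87	8.58	0.49	5.02	10.41	7.57	0.37	5.5	9.02
C20:0	Arachidic acid	mg/100g of fat	0.22	0.03	0.1	0.34	0.21	0.02	0.12	0.29	0.21	0.02	0.1	0.35
C22:0	Behenic acid	mg/100g of fat	0.05	0	0.02	0.07	0.04	0	0.02	0.05	0.04	0	0.03	0.05
C23:0	Tricosanoic acid	mg/100g of fat	0.04	0	0.02	0.05	0.03	0	0.01	0.06	0.04	0	0.02	0.05
C24:0	Lignoceric acid	mg/100g of fat	0.04	0	0.03	0.05	0.03	0	0.01	0.04	0.03	0	0.01	0.05
C14:1total	Myristoleic acid	mg/100g of fat	11	1.13	0.28	1.2	10	1.6	0.25	1.02	11	1.79	0.46	0.98
C16:1total	Palmitoleic acid	mg/100g of fat	1.31	0.06	1.1	1.71	1.65	0.23	0.42	3.08	1.82	0.18	1.21	2.84
C18:1n9c	Oleic acid	mg/100g of fat	19.06	1.35	10.7	24	25.91	1.12	20.08	33.2	22.57	0.7	19.4	26
C20:2	Eicosadienoic acid	mg/100g of fat	0.03	0	0.02	0.05	0.07	0.01	0.01	0.14	0.08	0.01	0.04	0.13
C22:5n3	Docosapentaenoic acid	mg/100g of fat	0.06	0.01	0.02	0.16	0.23	0.04	0.04	0.47	0.14	0.03	0.03	0.32
C22:6n3	Docosahexaenoic acid	mg/100g of fat	0.14	0	0.12	0.16	0.18	0.01	0.13	0.23	0.18	0.01	0.12	0.26
C18:3n3n	alpha linolenic acid	mg/100g of fat	0.27	0.02	0.2	0.42	0.32	0.02	0.19	0.4	0.21	0.03	0.1	0.49
CLA:9,11	Cis-9, trans-11 CLA	mg/100g of fat	0.3	0.02	0.16	0.41	0.33	0.02	0.22	0.39	0.31	0.04	0.15	0.54
CLA:10,12	Trans-10, cis-12 CLA	mg/100g of fat	0.02	0	0.01	0.03	0.04	0	0.03	0.07	0.04	0	0.02	0.06
MUFA	Sum of Monounsaturated fatty acids	mg/100g of fat	22.99	1.38	15.18	28.33	30.59	1.17	24.53	37.83	27.55	0.9	24.32	32.59
SFA	Sum of saturated fatty acids	mg/100g of fat	61.12	0.96	57.42	66.05	43.73	1.49	36.32	51.9	42.7	1.49	35.61	49.1
PUFA	Sum of Polyunsaturated fatty acids	mg/100g of fat	0.84	0.03	0.63	0.99	1.17	0.07	0.82	1.52	0.96	0.1	0.57	1.63
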