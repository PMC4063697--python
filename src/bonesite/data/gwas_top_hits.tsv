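TRAIT	RSID	LOCUS	POS	GENE	EA	EAF_A	BETA_A	SE_A	P_A	EAF_B	BETA_B	SE_B	P_B	EAF_M	BETA_M	SE_M	P_M	I2	P_HET
TBLH	rs3765350	1p36.12	22319903	WNT4	A	0.78	0.106	0.023	5.75e-6	0.78	0.109	0.026	2.92e-5	0.78	0.107	0.017	7.04e-10	0	9.32e-1
TBLH	rs6726821	2q24.3	166286360	GALNT3	T	0.51	0.094	0.019	1.32e-6	0.58	0.087	0.022	8.76e-5	0.54	0.091	0.015	3.95e-10	0	8.11e-1
TBLH	rs7776725	7q31.31	120820357	FAM3C	C	0.27	0.136	0.023	3.65e-9	0.26	0.188	0.026	7.67e-13	0.27	0.159	0.017	5.67e-20	54.7	1.38e-1
TBLH	rs7466269	9q34.11	132453905	FUBP3	A	0.64	0.094	0.020	3.72e-6	0.66	0.072	0.023	2.01e-3	0.65	0.084	0.015	3.26e-8	0	4.74e-1
TBLH	rs4420311	12p11.22	27875457	KLHDC5	G	0.47	0.080	0.020	7.84e-5	0.44	0.092	0.024	1.03e-4	0.46	0.085	0.016	4.44e-8	0	7.03e-1
TBLH	rs17536328	13q14.11	42041029	TNFSF11	T	0.43	0.079	0.020	6.14e-5	0.40	0.095	0.022	1.53e-5	0.42	0.086	0.015	7.58e-9	0	5.94e-1
TBLH	rs754388	14q32.12	92185163	RIN3	C	0.81	0.098	0.026	1.34e-4	0.83	0.149	0.031	1.41e-6	0.82	0.120	0.020	2.96e-9	36.0	2.11e-1
LL	rs3765350	1p36.12	22319903	WNT4	A	0.78	0.103	0.023	1.05e-5	0.78	0.090	0.026	5.74e-4	0.78	0.097	0.018	2.89e-8	0	7.12e-1
LL	rs2908004	7q31.31	120757005	WNT16	A	0.44	0.093	0.020	3.63e-6	0.50	0.108	0.022	1.25e-6	0.47	0.100	0.015	3.01e-11	0	6.19e-1
LL	rs7466269	9q34.11	132453905	FUBP3	A	0.64	0.097	0.020	1.85e-6	0.66	0.074	0.023	1.59e-3	0.65	0.087	0.015	1.51e-8	0	4.57e-1
LL	rs4420311	12p11.22	27875457	KLHDC5	G	0.47	0.086	0.020	2.06e-5	0.44	0.087	0.024	2.28e-4	0.46	0.086	0.016	3.21e-8	0	9.75e-1
LL	rs754388	14q32.12	92185163	RIN3	C	0.81	0.119	0.026	3.47e-6	0.83	0.145	0.031	2.51e-6	0.82	0.130	0.020	1.40e-10	0	5.26e-1
UL	rs2235529	1p36.12	22323074	WNT4	C	0.84	0.099	0.027	1.98e-4	0.85	0.140	0.031	5.99e-6	0.85	0.117	0.021	1.21e-8	0	3.22e-1
UL	rs6726821	2q24.3	166286360	GALNT3	T	0.51	0.078	0.019	6.44e-5	0.58	0.089	0.022	5.61e-5	0.54	0.083	0.015	1.13e-8	0	7.07e-1
UL	rs1262476	6q22.32	127028689	CENPW	G	0.76	0.130	0.022	6.37e-9	0.79	0.062	0.028	2.37e-2	0.77	0.104	0.018	2.93e-9	72.3	5.76e-2
UL	rs798943	7q31.31	120546135	CPED1	G	0.61	0.187	0.020	8.84e-21	0.62	0.205	0.023	1.28e-19	0.61	0.195	0.015	1.47e-37	0	5.57e-1
UL	rs9525638	13q14.11	42026577	TNFSF11	C	0.43	0.094	0.020	1.63e-6	0.41	0.083	0.022	1.52e-4	0.42	0.089	0.015	2.47e-9	0	7.13e-1
SK	rs3920498	1p36.12	22365474	WNT4	G	0.79	0.144	0.024	4.56e-9	0.82	0.118	0.030	8.40e-5	0.80	0.134	0.019	1.56e-12	0	5.01e-1
SK	rs2130604	6q22.32	126862254	CENPW	T	0.24	0.117	0.022	1.89e-7	0.23	0.106	0.026	6.47e-5	0.24	0.112	0.017	3.33e-11	0	7.48e-1
SK	rs3012465	6q23.2	133392629	EYA4	G	0.65	0.125	0.020	7.00e-10	0.69	0.129	0.023	3.06e-8	0.67	0.127	0.015	8.29e-17	0	8.96e-1
SK	rs13223036	7q31.31	120534544	CPED1	T	0.63	0.170	0.020	3.09e-17	0.65	0.167	0.023	6.21e-13	0.64	0.169	0.015	1.53e-28	0	9.22e-1
SK	rs2450083	8q24.12	120132723	COLEC10	T	0.48	0.105	0.020	1.66e-7	0.47	0.098	0.023	2.16e-5	0.47	0.102	0.015	2.13e-11	0	8.20e-1
SK	rs10835187	11p14.1	27462253	LIN7C	C	0.45	0.145	0.020	1.05e-13	0.50	0.106	0.022	1.63e-6	0.47	0.127	0.015	1.63e-17	41.1	1.93e-1
SK	rs12272917	11q13.2	68019946	PPP6R3	T	0.74	0.130	0.022	4.01e-9	0.76	0.080	0.026	2.52e-3	0.75	0.109	0.017	1.34e-10	53.0	1.45e-1
SK	rs884205	18q21.33	58205837	TNFRSF11A	C	0.72	0.092	0.023	5.38e-5	0.80	0.123	0.030	3.88e-5	0.75	0.104	0.018	1.84e-8	0	4.15e-1
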