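LOCUS	RSID	GENE	EA	BETA_LL	CIL_LL	CIU_LL	P_LL	BETA_UL	CIL_UL	CIU_UL	P_UL	BETA_SK	CIL_SK	CIU_SK	P_SK	CHI	FISHER_P
1p36.12	rs3765350	WNT4	A	0.097	0.06	0.13	2.89e-8	0.091	0.06	0.13	1.82e-7	0.115	0.08	0.15	3.56e-11	9.71	4.55e-2
1p36.12	rs2235529	WNT4	C	0.106	0.07	0.15	3.27e-7	0.117	0.08	0.16	1.21e-8	0.143	0.10	0.18	2.99e-12	8.34	7.99e-2
1p36.12	rs3920498	WNT4	G	0.075	0.04	0.11	8.41e-5	0.097	0.06	0.13	2.85e-7	0.134	0.10	0.17	1.56e-12	8.93	6.29e-2
2q24.3	rs6726821	GALNT3	T	0.078	0.05	0.11	1.03e-7	0.083	0.05	0.11	1.13e-8	0.031	0.00	0.06	3.37e-2	15.26	4.19e-3
6q22.32	rs1262476	CENPW	G	0.075	0.04	0.11	2.07e-5	0.104	0.07	0.14	2.93e-9	0.040	0.01	0.07	2.31e-2	27.26	1.76e-5
6q22.32	rs2130604	CENPW	T	0.018	-0.02	0.05	2.82e-1	0.038	0.01	0.07	2.42e-2	0.112	0.08	0.15	3.33e-11	15.09	4.51e-3
6q23.2	rs3012465	EYA4	G	0.019	-0.01	0.05	2.09e-1	0.051	0.02	0.08	7.45e-4	0.127	0.10	0.16	8.29e-17	35.66	3.40e-7
7q31.31	rs13223036	CPED1	T	0.020	-0.01	0.05	2.02e-1	0.187	0.16	0.22	1.25e-34	0.169	0.14	0.20	1.53e-28	178.00	2.01e-37
7q31.31	rs798943	CPED1	G	0.030	0.00	0.06	5.17e-2	0.195	0.17	0.23	1.47e-37	0.166	0.14	0.20	9.38e-28	171.73	4.44e-36
7q31.31	rs2908004	WNT16	A	0.100	0.07	0.13	3.01e-11	0.177	0.15	0.21	1.41e-32	0.088	0.06	0.12	3.59e-9	69.96	2.31e-14
8q24.12	rs2450083	COLEC10	T	0.015	-0.02	0.05	3.38e-1	0.037	0.01	0.07	1.42e-2	0.102	0.07	0.13	2.13e-11	26.62	2.37e-5
9q34.11	rs7466269	FUBP3	A	0.087	0.06	0.12	1.51e-8	0.077	0.05	0.11	3.67e-7	0.052	0.02	0.08	6.83e-4	2.40	6.63e-1
11p14.1	rs10835187	LIN7C	C	0.045	0.02	0.07	3.10e-3	0.041	0.01	0.07	5.53e-3	0.127	0.10	0.16	1.63e-17	38.35	9.47e-8
11q13.2	rs12272917	PPP6R3	T	0.065	0.03	0.10	1.38e-4	0.067	0.03	0.10	7.78e-5	0.109	0.08	0.14	1.34e-10	13.50	9.06e-3
12p11.22	rs4420311	KLHDC5	G	0.086	0.06	0.12	3.21e-8	0.066	0.04	0.10	2.25e-5	0.037	0.01	0.07	1.58e-2	9.78	4.43e-2
13q14.11	rs9525638	TNFSF11	C	0.064	0.04	0.09	2.09e-5	0.089	0.06	0.12	2.47e-9	0.057	0.03	0.09	1.43e-4	9.62	4.73e-2
14q32.12	rs754388	RIN3	C	0.130	0.09	0.17	1.40e-10	0.103	0.06	0.14	3.13e-7	0.035	0.00	0.08	7.82e-2	11.10	2.55e-2
18q21.33	rs884205	TNFRSF11A	C	0.003	-0.03	0.04	8.58e-1	0.023	-0.01	0.06	2.11e-1	0.104	0.07	0.14	1.84e-8	25.87	3.36e-5
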