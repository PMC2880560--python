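family_id	g	n	G	N	ov	ex	es
PF08522	93	0	12	0	590.68	7.15	0.18
PF07338	90	0	8	0	571.62	10.00	0.12
PF08481	61	0	6	0	387.43	8.71	0.09
PF08800	72	1	12	1	228.65	5.04	0.18
PF06603	33	0	6	0	209.59	4.71	0.09
PF02920	33	0	16	0	209.59	1.94	0.25
PF01848	29	0	7	0	184.19	3.63	0.11
PF06820	25	0	1	0	158.78	12.50	0.02
PF04971	20	0	7	0	127.03	2.50	0.11
PF09035	39	1	16	1	123.85	1.79	0.24
PF07980	784	54	13	6	90.54	48.29	0.19
PF00593	1285	2679	23	171	3.05	37.97	0.01
PF07715	1292	2686	24	172	3.05	36.15	0.02
PF00419	205	15	8	8	81.38	21.11	0.11
PF04122	102	281	2	20	2.30	20.62	-0.01
PF00005	4938	27601	65	493	1.14	18.95	0.00
PF00165	1982	3901	62	294	3.23	18.24	0.36
PF01554	1332	1965	63	347	4.30	15.17	0.27
PF07495	291	172	17	49	10.68	12.73	0.16
PF06820	25	0	1	0	158.78	12.50	0.02
PF02901	127	151	61	103	5.31	0.60	0.73
PF01228	179	219	62	114	5.17	0.94	0.72
PF04204	58	118	58	114	3.10	-0.04	0.66
PF02659	131	296	54	92	2.80	-0.80	0.64
PF02836	293	159	52	80	11.63	3.57	0.64
PF01183	103	106	49	62	6.11	0.38	0.63
PF06738	90	203	59	139	2.80	0.05	0.63
PF02837	397	218	52	92	11.51	5.15	0.61
PF00703	266	126	48	69	13.30	3.63	0.60
PF10509	58	150	56	135	2.44	-0.09	0.59
PB004588	105	0	14	0	666.89	7.00	0.22
PB064361	60	0	13	0	381.08	4.29	0.20
PB012771	92	1	21	1	292.16	3.68	0.32
PB008694	40	0	13	0	254.05	2.86	0.20
HGC00311	35	0	16	0	222.30	2.06	0.25
PB023339	32	0	13	0	203.24	2.29	0.20
HGC00150	31	0	15	0	196.89	1.94	0.23
PB029229	28	0	13	0	177.84	2.00	0.20
PB048420	27	0	18	0	171.49	1.42	0.28
PB047024	24	0	22	0	152.43	1.04	0.34
PB155142	930	158	14	58	37.15	59.32	0.10
HGC00106	908	76	14	8	74.90	52.09	0.20
HGC00024	819	56	14	6	91.26	46.60	0.20
PB001404	764	61	13	5	78.27	44.40	0.19
PB004588	105	0	14	0	666.89	7.00	0.22
PB064361	60	0	13	0	381.08	4.29	0.20
PB012771	92	1	21	1	292.16	3.68	0.32
PB000790	98	17	13	4	34.58	3.60	0.19
PB202086	21	0	5	0	133.38	3.50	0.08
PB001565	41	53	41	24	4.82	-1.14	0.58
HGC00044	204	186	44	88	6.93	2.44	0.50
PB004476	68	105	37	61	4.07	0.10	0.45
PB000119	129	274	45	129	2.98	0.70	0.43
PB001934	34	45	33	44	4.69	0.00	0.42
PB019388	29	38	29	34	4.72	-0.12	0.38
PB015954	36	3	23	3	57.16	0.75	0.35
PB001030	27	36	27	36	4.63	-0.01	0.34
PB047024	24	0	22	0	152.43	1.04	0.34
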