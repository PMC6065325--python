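rank	gene	bc	curated_flag	group	norm_masa	norm_wd
1	Hsp90ab1	0.2127	1	G4	0.94	0.51
2	Akt1	0.1694	1	G2	1.58	0.80
3	Src	0.1171	1	G2	1.31	0.66
4	Ranbp2	0.0671	0	G5	0.77	1.39
5	Mapk14	0.0586	0	G4	0.96	0.58
6	Egfr	0.0568	0	G2	1.30	0.67
7	Prkacb	0.0447	1	G2	1.23	0.65
8	Gnb2l1	0.0436	0	G6	0.78	0.45
9	Cav1	0.0419	0	G2	3.53	0.52
10	Cdh1	0.0385	1	G4	1.04	0.50
11	Cct7	0.0363	0	G6	0.85	0.54
12	Itgb1	0.0322	0	G2	2.02	1.16
13	Ppp1ca	0.0319	1	G6	0.81	0.50
14	Actr1a	0.0313	0	G4	0.99	0.51
15	Tgfb1	0.0313	1	G2	1.75	0.34
16	Sec61a1	0.0290	1	G6	0.73	0.31
17	Cdk16	0.0274	0	G6	0.85	0.51
18	Ywhab	0.0262	1	G6	0.76	0.52
19	Sdc2	0.0250	0	G2	1.77	0.67
20	Psmd2	0.0236	0	G6	0.77	0.45
21	Jak1	0.0232	0	G2	1.83	1.05
22	Rela	0.0232	0	G4	1.04	0.56
23	Vcp	0.0218	1	G6	0.78	0.51
24	Srebf2	0.0211	0	G4	0.94	0.55
25	Atp5a1	0.0206	0	G6	0.79	0.44
26	Nrp1	0.0201	1	G2	1.87	0.63
27	App	0.0197	1	G2	2.71	0.83
28	Eef1g	0.0197	1	G6	0.77	0.33
29	Stat5a	0.0191	0	G2	2.18	0.64
30	Itch	0.0187	0	G2	1.22	0.87
31	Atp1a1	0.0183	0	G2	1.80	0.63
32	Zmiz1	0.0176	0	G2	1.72	0.68
33	Gli1	0.0161	0	G2	3.78	1.42
34	Prkg2	0.0158	1	G6	0.51	0.09
35	Ctbp2	0.0153	0	G2	1.24	0.92
36	Hadhb	0.0147	1	G6	0.69	0.48
37	Nfkb2	0.0144	0	G2	1.57	0.85
38	Stk11	0.0143	0	G6	0.82	0.43
39	Vcl	0.0141	0	G2	1.73	0.73
40	Pip4k2b	0.0136	1	G2	1.46	0.74
41	Tle3	0.0134	1	G6	0.70	0.35
42	Map3k3	0.0133	0	G2	1.41	0.72
43	Fbxw11	0.0129	0	G2	1.16	0.68
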