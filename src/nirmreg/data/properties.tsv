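property	accession	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
h	KYTJ820101	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
M_v	GRAR740103	31	55	54	83	132	3	96	111	119	111	105	56	32.5	85	124	32	61	84	170	136
H_p	MANP780101	12.97	14.63	10.85	11.89	14.00	12.43	12.16	15.67	11.36	14.90	14.39	11.42	11.37	11.76	11.72	11.23	11.69	15.71	13.93	13.42
p_zim	ZIMJ680103	0.00	1.48	49.70	49.90	0.35	0.00	51.60	0.13	49.50	0.13	1.43	3.38	1.58	3.53	52.00	1.67	1.66	0.13	2.10	1.61
P_alpha	CHOP780201	1.42	0.70	1.01	1.51	1.13	0.57	1.00	1.08	1.16	1.21	1.45	0.67	0.57	1.11	0.98	0.77	0.83	1.06	1.08	0.69
p	GRAR740102	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
c	GRAR740101	0.00	2.75	1.38	0.92	0.00	0.74	0.58	0.00	0.33	0.00	0.00	1.33	0.39	0.89	0.65	1.42	0.71	0.00	0.13	0.20
P_beta	CHOP780202	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.60	0.74	1.30	1.05	0.89	0.55	1.10	0.93	0.75	1.19	1.70	1.37	1.47
B_l	ZIMJ680102	11.50	13.46	11.68	13.57	19.80	3.40	13.69	21.40	15.71	21.40	16.25	12.82	17.43	14.45	14.28	9.47	15.77	21.57	21.67	18.03
pH_i	ZIMJ680104	6.00	5.05	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.30	5.65	10.76	5.68	5.66	5.96	5.89	5.66
M_w	FASG760101	89.09	121.15	133.10	147.13	165.19	75.07	155.16	131.17	146.19	131.17	149.21	132.12	115.13	146.15	174.20	105.09	119.12	117.15	204.24	181.19
V0	COHE430101	0.748	0.631	0.579	0.643	0.774	0.632	0.670	0.884	0.789	0.884	0.708	0.619	0.758	0.674	0.666	0.613	0.689	0.847	0.734	0.712
P_r	WOEC730101	7.0	4.8	13.0	12.5	5.0	7.9	8.4	4.9	10.1	4.9	5.3	10.0	6.6	8.6	9.1	7.5	6.6	5.6	5.2	5.4
mu	MCMT640101	4.34	35.77	12.00	17.26	29.40	0.00	21.81	19.06	21.29	18.78	21.64	13.28	10.93	17.56	26.66	6.35	11.01	13.92	42.53	31.53
P	CHOP780101	0.66	1.19	1.46	0.74	0.60	1.56	0.95	0.47	1.01	0.59	0.60	1.56	1.52	0.98	0.95	1.43	0.96	0.50	0.96	1.14
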