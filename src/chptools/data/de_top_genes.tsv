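gene_id	comparison	mean_control	mean_kd	reported_fold	p_adj
Igkv1-135	LV_cond	0.6	33	61	0.0000
Slc1a6	LV_cond	2.1	82	39	0.0000
Mup5	LV_cond	123	4119	34	0.0000
Gpx3	LV_cond	295	7229	25	0.0000
Ighv1-67	LV_cond	1.6	36	22	0.0000
Saa3	LV_cond	2.2	47	22	0.0000
Tnfrsf11b	LV_cond	6.3	116	18	0.0000
Cacnb3	LV_cond	24	325	13	0.0000
Ndnf	LV_cond	89	1098	12	0.0000
Gm4841	LV_cond	3.8	44	12	0.0000
Ngfr	LV_cond	444	83	-5.3	0.0000
Nrn1	LV_cond	1924	496	-3.9	0.0000
B3galt2	LV_cond	109	31	-3.6	0.0007
Dazl	LV_cond	207	60	-3.4	0.0000
Itga10	LV_cond	184	54	-3.4	0.0000
Slc26a7	LV_cond	1670	533	-3.1	0.0000
Steap1	LV_cond	2224	735	-3.0	0.0000
Defb11	LV_cond	473	169	-2.8	0.0000
Entpd3	LV_cond	240	87	-2.8	0.0001
Ccl9	LV_cond	2037	774	-2.6	0.0000
9030619P08Rik	FourV_cond	0.00	28.6	inf	0.0000
Tmigd1	FourV_cond	0.00	33.1	inf	0.0000
A730020M07Rik	FourV_cond	1.3	76	61	0.0000
Gpx3	FourV_cond	181	10780	59	0.0000
Cacnb3	FourV_cond	18	778	43	0.0000
Mup5	FourV_cond	26	1053	41	0.0000
Fmod	FourV_cond	286	8688	30	0.0000
Slitrk6	FourV_cond	4.7	125	27	0.0000
Ndnf	FourV_cond	84	2070	25	0.0000
Adcy8	FourV_cond	10	233	23	0.0000
Ngfr	FourV_cond	684	159	-4.3	0.0000
Steap1	FourV_cond	1225	326	-3.8	0.0000
Elfn1	FourV_cond	104	28	-3.7	0.0000
Gnmt	FourV_cond	122	33	-3.7	0.0000
Gm22650	FourV_cond	141	40	-3.5	0.0000
Mir448	FourV_cond	95	28	-3.4	0.0002
Igf2os	FourV_cond	89	26	-3.4	0.0005
B3galt2	FourV_cond	141	44	-3.2	0.0000
Slc26a7	FourV_cond	843	271	-3.1	0.0000
Crhr2	FourV_cond	504	164	-3.1	0.0000
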