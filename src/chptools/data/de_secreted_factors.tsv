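gene_id	comparison	mean_control	mean_kd	reported_fold	p_adj
Bmp7	LV_cond	5125	7090	1.4	0.1845
Bmp7	FourV_cond	2547	4036	1.6	0.0014
Bmp7	FourV_GFP	2215	2261	1.0	1
Wnt2b	LV_cond	10	66	6.6	0.0002
Wnt2b	FourV_cond	12	66	5.4	0.0001
Wnt2b	FourV_GFP	29	35	1.2	1
Tgm2	LV_cond	276	422	1.5	0.2496
Tgm2	FourV_cond	138	265	1.9	0.0040
Tgm2	FourV_GFP	388	404	1.0	1
Sfrp1	LV_cond	8536	4511	0.53	0.0000
Sfrp1	FourV_cond	5121	2726	0.53	0.0000
Sfrp1	FourV_GFP	4087	2001	0.49	0.0392
Sostdc1	LV_cond	8627	4429	0.51	0.0000
Sostdc1	FourV_cond	5412	2793	0.52	0.0076
Sostdc1	FourV_GFP	8932	8458	1.1	1
Shh	LV_cond	0	1.4	inf	1
Shh	FourV_cond	0.7	4.6	6.6	1
Shh	FourV_GFP	0	64	inf	0.0000
Slit2	LV_cond	2302	2674	1.2	1
Slit2	FourV_cond	3471	4803	1.4	0.7159
Slit2	FourV_GFP	4323	6099	1.4	0.6487
Fgf2	LV_cond	140	123	0.88	1
Fgf2	FourV_cond	64	84	1.3	0.9878
Fgf2	FourV_GFP	67	66	1.0	1
Areg	LV_cond	0	0.9	inf	1
Areg	FourV_GFP	0	0	NA	NA
Tgfa	LV_cond	2140	1425	0.67	0.0620
Tgfa	FourV_cond	1357	999	0.74	0.1611
Tgfa	FourV_GFP	1040	1673	1.6	0.2163
Tgfb2	LV_cond	9233	4747	0.51	0.0000
Tgfb2	FourV_cond	3755	2169	0.58	0.0000
Tgfb2	FourV_GFP	3324	2563	0.77	0.3602
Igf2	LV_cond	42336	19144	0.45	0.0008
Igf2	FourV_cond	18717	8087	0.43	0.0000
Igf2	FourV_GFP	42542	17197	0.40	0.0000
Igfbp2	LV_cond	30195	20992	0.70	0.3255
Igfbp2	FourV_cond	28166	13235	0.47	0.0003
Igfbp2	FourV_GFP	47529	21660	0.46	0.0000
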