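protein_id	structure	replicate	otx2_peptides	igg_peptides
ACIN1	SVZ	1	3	0
ACIN1	RMS	1	11	1
ACIN1	VCx	1	16	4
ACIN1	ChP	1	0	0
ACOT11	SVZ	1	4	0
ACOT11	RMS	1	5	0
ACOT11	VCx	1	8	1
ACOT11	ChP	1	34	7
ARCN1	SVZ	1	3	1
ARCN1	RMS	1	7	2
ARCN1	VCx	1	4	1
ARCN1	ChP	1	0	0
DDX46	SVZ	1	30	0
DDX46	RMS	1	45	1
DDX46	VCx	1	34	3
DDX46	ChP	1	0	0
EIF4A3	SVZ	1	4	0
EIF4A3	RMS	1	10	2
EIF4A3	VCx	1	11	5
EIF4A3	ChP	1	0	0
FIG4	SVZ	1	20	0
FIG4	RMS	1	26	0
FIG4	VCx	1	27	0
FIG4	ChP	1	43	0
KCND3	SVZ	1	6	0
KCND3	RMS	1	5	0
KCND3	VCx	1	7	0
KCND3	ChP	1	6	0
PIKFYVE	SVZ	1	36	0
PIKFYVE	RMS	1	42	0
PIKFYVE	VCx	1	59	0
PIKFYVE	ChP	1	122	1
RBM25	SVZ	1	5	0
RBM25	RMS	1	11	1
RBM25	VCx	1	12	3
RBM25	ChP	1	0	0
SF3A1	SVZ	1	3	0
SF3A1	RMS	1	11	3
SF3A1	VCx	1	13	6
SF3A1	ChP	1	0	0
SF3B1	SVZ	1	3	0
SF3B1	RMS	1	22	0
SF3B1	VCx	1	25	9
SF3B1	ChP	1	0	0
SNRNP200	SVZ	1	5	0
SNRNP200	RMS	1	14	1
SNRNP200	VCx	1	31	4
SNRNP200	ChP	1	0	0
THOC2	SVZ	1	3	0
THOC2	RMS	1	5	0
THOC2	VCx	1	3	0
THOC2	ChP	1	0	0
VAC14	SVZ	1	39	2
VAC14	RMS	1	49	3
VAC14	VCx	1	56	0
VAC14	ChP	1	75	0
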