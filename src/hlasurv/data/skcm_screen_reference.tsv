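# Published per-superallele screening summary for the 401-patient TCGA-SKCM
# melanoma cohort: carrier / non-carrier counts, mean overall survival (months)
# in each group, their difference (present - absent), and the two-sample
# t-test p-value. Values are reproduced as printed (mean_diff and p keep the
# published precision).
superallele	n_present	n_absent	mos_present	mos_absent	mean_diff	p
HLA-B*55	16	385	94.58	58.46	36.12	0.002
HLA-DPB1*01	34	367	87.51	57.34	30.17	6.82E-07
HLA-B*08	80	321	81.09	54.62	26.47	6.36E-14
HLA-DRB1*03	85	316	80.14	54.46	25.69	2.29E-14
HLA-B*49	11	390	77.87	59.39	18.48	0.037
HLA-A*01	115	286	72.88	54.68	18.2	1.24E-17
HLA-C*05	61	340	72.74	57.6	15.15	1.82E-12
HLA-DPB1*10	16	385	72.87	59.36	13.51	0.0004
HLA-C*07	217	184	66.01	52.7	13.31	3.65E-31
HLA-B*14	27	374	48.34	60.74	-12.39	2.20E-05
HLA-A*24	81	320	48.59	62.77	-14.18	5.61E-13
HLA-DPB1*05	17	384	46.26	60.51	-14.25	0.001
HLA-A*31	26	375	46.34	60.84	-14.5	1.76E-05
HLA-DPB1*11	10	391	45.32	60.27	-14.95	0.003
HLA-DRB1*07	103	298	48.37	63.89	-15.51	4.31E-14
HLA-DPB1*06	12	389	43.68	60.4	-16.72	0.014
HLA-C*14	10	391	43.44	60.32	-16.88	0.003
HLA-B*18	39	362	44.41	61.57	-17.16	1.07E-08
HLA-C*01	42	359	44.35	61.72	-17.37	9.08E-07
HLA-B*13	19	382	41.94	60.79	-18.86	0.03
HLA-A*30	26	375	42.14	61.13	-19	5.22E-06
HLA-DRB1*16	23	378	29.53	61.75	-32.22	7.00E-06
HLA-B*50	12	389	25.03	60.98	-35.95	6.33E-05
HLA-DRB1*12	19	382	23.46	61.71	-38.26	9.43E-05
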