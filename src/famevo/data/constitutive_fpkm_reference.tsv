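gene_id	root	root_hair	nodules	pod	seed	stem	sam	leaves	flower
GmLac5	29.87	66.04	33.99	37.23	14.55	46.41	24.14	2.00	6.78
GmLac10	11.59	44.89	11.61	73.40	111.75	53.38	23.71	2.26	11.45
GmLac12	54.73	65.77	60.52	23.36	22.16	47.63	55.08	6.07	5.52
GmLac16	36.50	49.47	10.29	129.80	4.81	99.05	114.40	14.28	18.43
GmLac40	33.53	59.28	40.51	33.92	10.26	87.08	43.94	6.10	9.01
GmLac55	162.50	50.75	30.23	12.38	3.09	36.75	8.77	12.19	4.63
GmLac62	27.32	53.26	32.22	21.12	15.68	33.04	8.42	1.00	2.10
GmLac65	69.51	127.58	54.73	26.11	33.73	26.31	62.91	1.39	4.16
GmLac66	66.83	56.05	48.36	56.52	35.88	84.13	43.27	8.40	9.79
GmLac69	47.09	65.88	29.72	2.73	0.36	28.53	16.04	3.85	4.14
GmLac85	93.65	67.15	30.28	32.47	44.21	48.51	13.49	12.04	2.55
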