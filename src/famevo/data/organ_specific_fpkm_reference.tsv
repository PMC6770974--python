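gene_id	root	root_hair	nodules	pod	seed	stem	sam	leaves	flower
GmLac1	41.64	4.94	6.82	0.06	0.00	0.04	0.01	0.03	0.14
GmLac2	0.94	6.30	12.58	10.45	0.45	70.53	3.31	5.93	1.92
GmLac8	2.95	4.36	3.94	7.97	0.69	32.58	0.56	0.98	1.91
GmLac9	1.00	7.28	15.93	10.78	0.61	75.27	3.25	5.62	2.18
GmLac24	38.53	11.66	21.13	0.08	0.00	0.03	0.09	2.86	0.21
GmLac25	0.20	0.00	0.00	0.01	0.00	1.06	0.20	0.03	505.03
GmLac77	0.16	1.65	2.13	35.66	0.05	16.90	0.30	1.16	0.32
GmLac87	13.60	0.03	0.00	0.00	0.01	2.87	117.91	0.00	2.54
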