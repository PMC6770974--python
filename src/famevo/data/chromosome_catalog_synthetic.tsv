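gene_id	chromosome
GmLac1	Chr01
GmLac2	Chr01
GmLac3	Chr01
GmLac4	Chr01
GmLac5	Chr01
GmLac6	Chr02
GmLac7	Chr02
GmLac8	Chr02
GmLac9	Chr03
GmLac10	Chr04
GmLac11	Chr04
GmLac12	Chr05
GmLac13	Chr05
GmLac14	Chr05
GmLac15	Chr06
GmLac16	Chr06
GmLac17	Chr06
GmLac18	Chr06
GmLac19	Chr06
GmLac20	Chr06
GmLac21	Chr07
GmLac22	Chr07
GmLac23	Chr07
GmLac24	Chr07
GmLac25	Chr07
GmLac26	Chr07
GmLac27	Chr07
GmLac28	Chr07
GmLac29	Chr08
GmLac30	Chr08
GmLac31	Chr08
GmLac32	Chr08
GmLac33	Chr08
GmLac34	Chr09
GmLac35	Chr11
GmLac36	Chr11
GmLac37	Chr11
GmLac38	Chr11
GmLac39	Chr11
GmLac40	Chr11
GmLac41	Chr11
GmLac42	Chr11
GmLac43	Chr11
GmLac44	Chr11
GmLac45	Chr12
GmLac46	Chr12
GmLac47	Chr12
GmLac48	Chr12
GmLac49	Chr13
GmLac50	Chr13
GmLac51	Chr13
GmLac52	Chr13
GmLac53	Chr13
GmLac54	Chr13
GmLac55	Chr13
GmLac56	Chr13
GmLac57	Chr13
GmLac58	Chr14
GmLac59	Chr14
GmLac60	Chr14
GmLac61	Chr14
GmLac62	Chr14
GmLac63	Chr15
GmLac64	Chr16
GmLac65	Chr17
GmLac66	Chr17
GmLac67	Chr17
GmLac68	Chr17
GmLac69	Chr17
GmLac70	Chr18
GmLac71	Chr18
GmLac72	Chr18
GmLac73	Chr18
GmLac74	Chr18
GmLac75	Chr18
GmLac76	Chr18
GmLac77	Chr18
GmLac78	Chr18
GmLac79	Chr18
GmLac80	Chr18
GmLac81	Chr18
GmLac82	Chr19
GmLac83	Chr19
GmLac84	Chr19
GmLac85	Chr20
GmLac86	Chr20
GmLac87	Chr20
GmLac88	Chr20
GmLac89	Chr20
GmLac90	Chr20
GmLac91	scaffold_27
GmLac92	scaffold_27
GmLac93	scaffold_614
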