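pattern	mirna	mean_G1	mean_G2	mean_G3	fc_21	fc_32	p_value
up	miR1850	56	53	293	0.95	5.53	7.40E-03
up	miR1874-5p	349	1140	1266	3.27	1.11	2.29E-05
up	miR1862e	133	378	384	2.84	1.02	3.69E-03
up	miR1862d	247	526	656	2.13	1.25	3.17E-03
up	miR1874-3p	2473	4684	5507	1.89	1.18	3.57E-03
up	miR1435	86	138	357	1.60	2.59	2.24E-03
up	miR1881	36	65	88	1.81	1.35	1.78E-03
up	*miR1867	109	219	186	2.01	0.85	3.14E-03
up	miR1884b	99	213	168	2.15	0.79	3.41E-03
down	miR171a	118	58	42	0.49	0.72	1.13E-03
down	miR171b-f	451	253	182	0.56	0.72	4.64E-03
down	miR530-5p	4522	3286	1514	0.73	0.46	4.18E-04
down	miR160f	125	38	31	0.30	0.82	1.27E-03
down	miR160a-d	251	69	38	0.27	0.55	8.01E-04
down	miR160e	275	68	48	0.25	0.71	1.16E-03
down	miR444b.2	770	443	63	0.58	0.14	3.68E-04
down	*miR1873	123	65	47	0.52	0.72	5.21E-05
down	miR2055	138	140	97	1.01	0.69	5.23E-03
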