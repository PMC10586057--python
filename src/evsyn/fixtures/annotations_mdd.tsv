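variant_id	missense_flag	sift_class	polyphen_class	regulome_rank	splice_flag	mirna_flag	conservation	reg_potential	ko_mouse	drug_target	brain_expressed
5-HTTLPR	false	na	na	na	false	false	0.3	0.1	true	true	true
rs6265	true	tolerated	possibly_damaging	7	false	false	0.85	0.1	true	true	true
rs4680	true	tolerated	benign	6	true	false	0.9	0.15	true	true	true
rs1801133	true	deleterious	probably_damaging	4	false	false	1.0	0.358	false	false	false
rs2242446	false	na	na	2b	false	false	0.82	0.55	true	true	false
rs5443	false	na	na	4	false	false	0.2	0.438	false	true	true
rs1045642	false	na	na	5	true	false	0.4	0.2	true	true	false
rs9340799	false	na	na	6	false	false	0.1	0.05	true	true	false
rs6295	false	na	na	4	false	false	0.0	0.0	true	true	true
rs2234693	false	na	na	5	false	false	0.35	0.12	true	true	true
rs4291	false	na	na	5	false	false	0.25	0.18	true	true	false
rs242939	false	na	na	5	false	false	0.0	0.238	true	true	true
rs6311	false	na	na	4	false	false	0.88	0.22	true	true	true
rs1360780	false	na	na	4	false	false	0.81	0.3	true	true	true
rs4713916	false	na	na	5	false	false	0.2	0.1	true	true	true
rs1800532	false	na	na	4	false	false	0.95	0.25	true	false	false
rs1006737	false	na	na	5	false	false	0.0	0.0	true	true	true
rs4880	true	tolerated	benign	4	true	false	0.0	0.22	true	false	false
rs1801131	true	tolerated	benign	1f	true	false	1.0	0.4	true	false	false
rs2522833	true	tolerated	benign	6	true	false	0.3	0.1	true	false	false
rs1800629	false	na	na	1d	false	false	0.45	0.45	true	false	false
rs4295	false	na	na	4	false	false	0.15	0.1	true	false	false
rs4343	false	na	na	2b	true	false	0.2	0.41	true	false	false
rs41423247	false	na	na	2b	false	false	0.0	0.62	true	true	true
rs2273289	false	na	na	2b	false	false	0.3	0.2	false	false	false
rs2715148	false	na	na	5	false	true	0.25	0.15	true	false	false
rs2423618	false	na	na	5	false	false	0.1	0.05	false	false	false
rs2715147	false	na	na	4	false	false	0.2	0.1	true	false	false
rs9416742	false	na	na	5	false	false	0.15	0.08	true	false	false
rs999845	false	na	na	5	false	false	0.12	0.06	true	false	false
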