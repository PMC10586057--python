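variant_id	missense_flag	sift_class	polyphen_class	regulome_rank	splice_flag	mirna_flag	conservation	reg_potential	ko_mouse	drug_target	brain_expressed
5-HTTLPR	false	na	na	na	false	false	0.3	0.1	true	true	true
STin2	false	na	na	na	false	false	NA	NA	true	true	true
rs6265	true	tolerated	possibly_damaging	4	false	false	0.85	0.1	true	true	true
rs7997012	false	na	na	4	false	false	0.2	0.15	true	true	true
rs6295	false	na	na	4	false	false	0.82	0.0	true	true	true
rs5443	false	na	na	4	false	false	0.2	0.438	true	true	true
rs334558	false	na	na	4	false	false	0.3	0.2	true	true	false
rs2470890	false	na	na	1f	false	false	0.25	0.45	true	true	true
rs6313	false	na	na	3a	false	false	0.4	0.3	true	true	true
rs2066713	false	na	na	4	false	false	0.2	0.1	true	true	false
rs41423247	false	na	na	2b	false	false	0.0	0.62	true	true	true
rs2171363	false	na	na	4	false	false	0.3	0.1	true	true	true
rs2075507	false	na	na	5	false	false	0.2	0.15	true	false	true
rs1954787	false	na	na	5	false	false	0.25	0.1	true	false	true
rs1360780	false	na	na	5	false	false	0.81	0.3	true	true	true
rs6046805	false	na	na	7	false	false	0.1	0.05	false	false	false
rs6966038	false	na	na	5	false	false	0.15	0.08	false	false	false
rs6127921	false	na	na	5	false	false	0.2	0.1	false	false	false
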