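variant_id	missense_flag	sift_class	polyphen_class	regulome_rank	splice_flag	mirna_flag	conservation	reg_potential	ko_mouse	drug_target	brain_expressed
rs1801133	true	deleterious	probably_damaging	4	false	false	1.0	0.358	false	false	false
rs5443	false	na	na	4	false	false	0.2	0.438	false	true	true
rs242939	false	na	na	5	false	false	0.0	0.238	true	true	true
rs1006737	false	na	na	5	false	false	0.0	0.0	true	true	true
rs4880	true	tolerated	benign	4	true	false	0.0	0.22	true	false	false
rs6295	false	na	na	4	false	false	0.0	0.0	true	true	true
rs1801131	true	tolerated	benign	1f	true	false	1.0	0.4	true	false	false
STin2	false	na	na	4	false	false	NA	NA	true	true	true
rs41423247	false	na	na	2b	false	false	0.0	0.62	true	true	true
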