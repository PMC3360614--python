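mirna	n_targets	n_class2
sli-miR-33a	2	0
sli-miR-33b	6	0
sli-miR-34	21	1
sli-miR-71	14	3
sli-miR-210	27	2
sli-miR-283	14	1
sli-miR-307	39	2
sli-miR-928a	39	6
sli-miR-928b	44	7
sli-miR-983	5	0
sli-miR-1890	0	0
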