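cazy_class	family_count	gene_count	read_count
AA	4	57	125248
CBM	27	227	545456
CE	11	250	483142
GH	102	643	2556056
GT	26	445	1005060
PL	14	36	154000
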