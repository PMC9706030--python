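section	family	gene_count	read_count
LMEs	AA2	1	1240
LMEs	AA4	15	56066
LMEs	AA6	39	66334
LMEs	AA7	2	1608
binding_modules	CBM3	7	28046
binding_modules	CBM4	3	21588
binding_modules	CBM6	6	37160
binding_modules	CBM9	9	6772
binding_modules	CBM16	9	52702
binding_modules	CBM23	1	108
binding_modules	CBM31	2	1040
binding_modules	CBM32	3	4634
binding_modules	CBM35	6	24400
binding_modules	CBM37	10	33850
binding_modules	CBM42	2	6504
binding_modules	CBM44	1	3110
binding_modules	CBM46	2	204
binding_modules	CBM51	4	6940
binding_modules	CBM54	3	560
binding_modules	CBM61	5	38294
binding_modules	CBM67	4	146
cellulases_hemicellulases	GH1	29	49444
cellulases_hemicellulases	GH3	29	100644
cellulases_hemicellulases	GH5	16	84872
cellulases_hemicellulases	GH8	1	4926
cellulases_hemicellulases	GH9	16	100654
cellulases_hemicellulases	GH16	3	4480
cellulases_hemicellulases	GH26	7	59378
cellulases_hemicellulases	GH30_8	1	4114
cellulases_hemicellulases	GH44	1	11206
cellulases_hemicellulases	GH48	3	20574
cellulases_hemicellulases	GH51	8	32728
cellulases_hemicellulases	GH74	7	40172
cellulases_hemicellulases	GH81	1	6332
cellulases_hemicellulases	GH116	1	1236
hemicellulases	GH2	25	168714
hemicellulases	GH4	22	47864
hemicellulases	GH10	20	141490
hemicellulases	GH11	1	7380
hemicellulases	GH27	1	8546
hemicellulases	GH29	6	25280
hemicellulases	GH31	14	47634
hemicellulases	GH35	2	16812
hemicellulases	GH36	11	61974
hemicellulases	GH37	1	11212
hemicellulases	GH38	8	26766
hemicellulases	GH39	6	38952
hemicellulases	GH42	8	15742
hemicellulases	GH43	23	139416
hemicellulases	GH52	1	11314
hemicellulases	GH53	5	46350
hemicellulases	GH76	7	17582
hemicellulases	GH78	3	156
hemicellulases	GH95	11	44410
hemicellulases	GH106	8	55788
hemicellulases	GH113	1	1470
hemicellulases	GH120	5	17812
hemicellulases	GH125	1	12
hemicellulases	GH127	3	31670
hemicellulases	GH137	2	38
hemicellulases	GH141	1	9140
hemicellulases	GH142	1	56
hemicellulases_pectin	CE1	44	60674
hemicellulases_pectin	CE3	17	39112
hemicellulases_pectin	CE4	95	152940
hemicellulases_pectin	CE6	1	978
hemicellulases_pectin	CE7	16	50096
hemicellulases_pectin	CE8	8	16440
hemicellulases_pectin	CE9	20	47026
hemicellulases_pectin	CE10	21	53606
hemicellulases_pectin	CE12	11	26316
hemicellulases_pectin	GH28	5	28470
hemicellulases_pectin	GH67	4	29962
hemicellulases_pectin	GH88	2	9944
hemicellulases_pectin	GH105	10	49172
hemicellulases_pectin	GH115	1	12512
hemicellulases_pectin	GH138	2	2772
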