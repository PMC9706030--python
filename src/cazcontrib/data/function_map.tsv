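family	cazy_class	category	section	subfamily_rollup	listed	source_note
AA2	AA	lignin_AA	LMEs	0	1	peroxidases
AA4	AA	lignin_AA	LMEs	0	1	vanillyl-alcohol oxidase
AA6	AA	lignin_AA	LMEs	0	1	benzoquinone reductase
AA7	AA	lignin_AA	LMEs	0	1	oligosaccharide oxidase
CBM3	CBM	binding_module	binding_modules	0	1	cellulose
CBM4	CBM	binding_module	binding_modules	0	1	cellulose/xylan/glucan
CBM6	CBM	binding_module	binding_modules	0	1	cellulose/xylan
CBM9	CBM	binding_module	binding_modules	0	1	xylan/cellulose
CBM16	CBM	binding_module	binding_modules	0	1	cellulose/glucomannan
CBM23	CBM	binding_module	binding_modules	0	1	mannan
CBM31	CBM	binding_module	binding_modules	0	1	beta-1,3-xylan
CBM32	CBM	binding_module	binding_modules	0	1	galactose/lactose
CBM35	CBM	binding_module	binding_modules	0	1	xylan/mannan/galactan
CBM37	CBM	binding_module	binding_modules	0	1	cellulose/xylan
CBM42	CBM	binding_module	binding_modules	0	1	arabinoxylan
CBM44	CBM	binding_module	binding_modules	0	1	cellulose/xyloglucan
CBM46	CBM	binding_module	binding_modules	0	1	cellulose
CBM51	CBM	binding_module	binding_modules	0	1	galactose
CBM54	CBM	binding_module	binding_modules	0	1	xylan/glucan
CBM61	CBM	binding_module	binding_modules	0	1	beta-1,4-galactan
CBM67	CBM	binding_module	binding_modules	0	1	L-rhamnose
GH1	GH	beta_glucosidase	cellulases_hemicellulases	0	1	
GH1	GH	beta_xylosidase	cellulases_hemicellulases	0	1	
GH1	GH	beta_mannanase	cellulases_hemicellulases	0	1	
GH1	GH	galactosidase	cellulases_hemicellulases	0	1	
GH1	GH	glucuronidase	cellulases_hemicellulases	0	0	beta-glucuronidase activity; not in the 7-family xylan glucuronidase list
GH3	GH	beta_glucosidase	cellulases_hemicellulases	0	1	
GH3	GH	beta_xylosidase	cellulases_hemicellulases	0	1	
GH3	GH	alpha_fucosidase	cellulases_hemicellulases	0	1	
GH5	GH	endoglucanase	cellulases_hemicellulases	1	1	subfamilies GH5_1 GH5_2 GH5_4 GH5_19 GH5_22 GH5_25 GH5_34 GH5_35 GH5_36 GH5_37
GH5	GH	exoglucanase	cellulases_hemicellulases	1	1	cellobiohydrolase
GH5	GH	beta_glucosidase	cellulases_hemicellulases	1	1	
GH5	GH	endo_xylanase	cellulases_hemicellulases	1	1	
GH5	GH	beta_mannanase	cellulases_hemicellulases	1	1	beta-mannosidase/mannanase
GH8	GH	endoglucanase	cellulases_hemicellulases	0	1	
GH8	GH	endo_xylanase	cellulases_hemicellulases	0	1	
GH9	GH	endoglucanase	cellulases_hemicellulases	0	1	
GH9	GH	exoglucanase	cellulases_hemicellulases	0	1	cellobiohydrolase
GH9	GH	beta_glucosidase	cellulases_hemicellulases	0	1	
GH16	GH	endoglucanase	cellulases_hemicellulases	0	1	endo-1,3(4)-beta-glucanase
GH16	GH	galactosidase	cellulases_hemicellulases	0	1	endo-beta-1,4-galactosidase
GH26	GH	endoglucanase	cellulases_hemicellulases	0	1	
GH30_8	GH	beta_glucosidase	cellulases_hemicellulases	0	1	
GH30_8	GH	endo_xylanase	cellulases_hemicellulases	0	1	
GH30_8	GH	beta_xylosidase	cellulases_hemicellulases	0	1	
GH30_8	GH	glucuronidase	cellulases_hemicellulases	0	0	beta-glucuronidase activity; not in the 7-family list
GH44	GH	endoglucanase	cellulases_hemicellulases	0	1	
GH48	GH	endoglucanase	cellulases_hemicellulases	0	1	
GH48	GH	exoglucanase	cellulases_hemicellulases	0	1	cellobiohydrolase
GH51	GH	endoglucanase	cellulases_hemicellulases	0	1	
GH51	GH	endo_xylanase	cellulases_hemicellulases	0	1	
GH51	GH	beta_xylosidase	cellulases_hemicellulases	0	1	
GH51	GH	arabinofuranosidase	cellulases_hemicellulases	0	1	
GH74	GH	endoglucanase	cellulases_hemicellulases	0	1	
GH74	GH	exoglucanase	cellulases_hemicellulases	0	1	cellobiohydrolase
GH81	GH	endoglucanase	cellulases_hemicellulases	0	1	endo-beta-1,3-glucanase
GH116	GH	beta_glucosidase	cellulases_hemicellulases	0	1	
GH116	GH	beta_xylosidase	cellulases_hemicellulases	0	1	
GH2	GH	beta_mannanase	hemicellulases	0	1	beta-mannosidase
GH2	GH	arabinofuranosidase	hemicellulases	0	1	
GH2	GH	galactosidase	hemicellulases	0	1	beta-galactosidase
GH4	GH	galactosidase	hemicellulases	0	1	alpha-galactosidase
GH4	GH	glucuronidase	hemicellulases	0	1	alpha-glucuronidase
GH10	GH	endo_xylanase	hemicellulases	0	1	
GH11	GH	endo_xylanase	hemicellulases	0	1	
GH27	GH	galactosidase	hemicellulases	0	1	alpha-galactosidase
GH29	GH	alpha_fucosidase	hemicellulases	0	1	
GH31	GH	galactosidase	hemicellulases	0	1	alpha-galactosidase
GH35	GH	galactosidase	hemicellulases	0	1	beta-galactosidase
GH36	GH	galactosidase	hemicellulases	0	1	alpha-galactosidase
GH37	GH		hemicellulases	0		alpha-trehalase; no lignocellulolytic category
GH38	GH	alpha_mannosidase	hemicellulases	0	1	
GH39	GH	beta_xylosidase	hemicellulases	0	1	
GH42	GH	galactosidase	hemicellulases	0	1	beta-galactosidase
GH43	GH	beta_xylosidase	hemicellulases	1	1	subfamilies GH43_1 GH43_2 GH43_4 GH43_10 GH43_11 GH43_12 GH43_17 GH43_20 GH43_22 GH43_24 GH43_26 GH43_27 GH43_29 GH43_35
GH43	GH	arabinofuranosidase	hemicellulases	1	1	
GH52	GH	beta_xylosidase	hemicellulases	0	1	
GH53	GH	galactosidase	hemicellulases	0	1	endo-beta-1,4-galactanase
GH76	GH		hemicellulases	0		alpha-1,6-mannanase; no lignocellulolytic category
GH78	GH	alpha_rhamnosidase	hemicellulases	0	1	
GH95	GH	alpha_fucosidase	hemicellulases	0	1	
GH95	GH	galactosidase	hemicellulases	0	1	alpha-L-galactosidase
GH106	GH	alpha_rhamnosidase	hemicellulases	0	1	
GH113	GH		hemicellulases	0		beta-mannanase by class description; main-chain mannan category follows the 3-family curated list
GH120	GH	beta_xylosidase	hemicellulases	0	1	
GH125	GH	alpha_mannosidase	hemicellulases	0	1	exo-alpha-1,6-mannosidase
GH127	GH	arabinofuranosidase	hemicellulases	0	1	beta-L-arabinofuranosidase
GH137	GH	arabinofuranosidase	hemicellulases	0	1	beta-L-arabinofuranosidase
GH141	GH	alpha_fucosidase	hemicellulases	0	1	
GH142	GH	arabinofuranosidase	hemicellulases	0	1	beta-L-arabinofuranosidase
CE1	CE	esterase	hemicellulases_pectin	0	1	acetyl xylan/feruloyl esterase
CE3	CE	esterase	hemicellulases_pectin	0	1	acetyl xylan esterase
CE4	CE	esterase	hemicellulases_pectin	0	1	acetyl xylan esterase
CE6	CE	esterase	hemicellulases_pectin	0	1	acetyl xylan esterase
CE7	CE	esterase	hemicellulases_pectin	0	1	acetyl xylan esterase
CE8	CE	esterase	hemicellulases_pectin	0	1	pectin methylesterase
CE9	CE	esterase	hemicellulases_pectin	0	1	N-acetylglucosamine 6-phosphate deacetylase
CE10	CE	esterase	hemicellulases_pectin	0	1	arylesterase/carboxylesterase
CE12	CE	esterase	hemicellulases_pectin	0	1	rhamnogalacturonan acetylesterase
GH28	GH	glucuronidase	hemicellulases_pectin	0	1	polygalacturonase/rhamnogalacturonase
GH67	GH	glucuronidase	hemicellulases_pectin	0	1	xylan alpha-1,2-glucuronidase
GH88	GH	glucuronidase	hemicellulases_pectin	0	1	beta-glucuronyl hydrolase
GH105	GH	glucuronidase	hemicellulases_pectin	0	1	rhamnogalacturonyl hydrolase
GH105	GH	alpha_rhamnosidase	hemicellulases_pectin	0	1	third rhamnose-active family completing the 3-family count
GH115	GH	glucuronidase	hemicellulases_pectin	0	1	xylan alpha-1,2-glucuronidase
GH138	GH	glucuronidase	hemicellulases_pectin	0	1	alpha-galacturonidase
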