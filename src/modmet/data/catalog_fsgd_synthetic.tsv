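module_id	name	pathway	ko_groups	substrates	products	direction
P1	formate dehydrogenase (NADP+)	WLP	K05299|K15022		formate	none
P2	formate dehydrogenase (ferredoxin)	WLP	K00122|K00123|K00124|K22015|K22016		formate	none
P3	formaldehyde dehydrogenase	WLP	K00121;K00148		formate	none
P4	S-formylglutathione hydrolase	WLP	K01069;K01070		formate	none
P5	formyltetrahydrofolate deformylase	WLP	K01433;K13990		formate	none
P6	formate--tetrahydrofolate ligase	WLP	K01938	formate		none
P7	methyl branch + CO dehydrogenase/acetyl-CoA synthase	WLP	K01491|K00297|K00192|K00193|K00194|K00195|K00196|K00197|K14138|K00198|K15023		acetyl-CoA	none
P8	glycine cleavage system (reductive direction)	rGly_Ser	K00281;K00282;K00283|K00605|K02437|K00382	formate	glycine	none
P9	serine hydroxymethyltransferase	rGly_Ser	K00600	glycine	serine	none
P10	phosphoserine phosphatase (serB)	rGly_Ser	K01079		serine	none
P11	pyruvate formate-lyase	fermentation	K00656|K04069	pyruvate	formate;acetyl-CoA	none
P12	D-lactate dehydrogenase	fermentation	K03777;K03778	pyruvate	lactate	none
P13	L-lactate dehydrogenase	fermentation	K00016	pyruvate	lactate	none
P14	L-serine deaminase	fermentation	K01752	serine	pyruvate	none
P15	lactate utilization complex LldEFG	fermentation	K00101;K18928|K00102;K18929|K18930	lactate	pyruvate	none
P16	pyruvate:ferredoxin oxidoreductase (porABCD)	fermentation	K00169|K00170|K00171|K00172	acetate	pyruvate	none
P17	glycine reductase complex	fermentation	K10670|K21576;K21578|K21577;K21579	glycine	pyruvate	none
P18	phosphate acetyltransferase	PAT_ACK	K00625	acetyl-CoA		none
P19	acetate kinase	PAT_ACK	K00925		acetate	none
P20	acetaldehyde dehydrogenase (acylating)	fermentation	K00132;K04021		acetyl-CoA	none
P21	aldehyde-alcohol dehydrogenase AdhE	fermentation	K04072;K13954		acetyl-CoA	none
P22	acetyl-CoA synthetase (AMP-forming)	fermentation	K01895	acetate	acetyl-CoA	none
P23	acetate-CoA ligase (ADP-forming)	fermentation	K01905|K22224	acetate	acetyl-CoA	none
P24	pyruvate oxidase	fermentation	K00156;K00158	pyruvate	acetate	none
P25	pyruvate synthase (ferredoxin)	rTCA	K00186;K03737|K00187|K00188|K00189	acetyl-CoA	pyruvate	none
P26	PEP carboxykinase	rTCA	K01596;K01610	pyruvate	OAA	none
P27	PEP carboxylase	rTCA	K01595	pyruvate	OAA	none
P28	pyruvate carboxylase	rTCA	K01958;K01959|K01958;K01960	pyruvate	OAA	none
P29	aspartate transaminase / aspartate dehydrogenase	rTCA	K00812;K00813;K06447	OAA;aspartate	aspartate;OAA	none
P30	malate dehydrogenase (OAA-reducing)	rTCA	K00024;K00025;K00026	OAA	malate	none
P31	fumarate hydratase	rTCA	K01676;K01677;K01679|K01676;K01678;K01679	malate	fumarate	none
P32	malic enzyme (malate to pyruvate)	anaplerotic	K00029	malate	pyruvate	none
P33	succinyl-CoA synthetase	rTCA	K01902|K01903	succinate		none
P34	aspartate ammonia-lyase	anaplerotic	K01744	fumarate;aspartate	aspartate;fumarate	none
P35	fumarate reductase	rTCA	K00239;K00244|K00240;K00245|K00241;K00246|K00242;K00247	fumarate	succinate	none
P36	4-hydroxybutyryl-CoA dehydratase branch	dicarboxylate_hydroxybutyrate	K14534|K15038|K15016|K15017	succinate	acetyl-CoA	none
P37	2-oxoglutarate:ferredoxin oxidoreductase (2OGOR)	rTCA	K00174;K00179|K00175;K00180	succinate	2OG	none
P38	aconitate hydratase	rTCA	K01681;K01682	citrate		none
P39	citryl-CoA synthetase/lyase	rTCA	K15232|K15233|K15234;K15235	citrate	acetyl-CoA;OAA	none
P40	ATP-citrate lyase (ACL)	rTCA	K15230|K15231	citrate	acetyl-CoA;OAA	none
P41	citrate synthase	rTCA	K01647;K05942	acetyl-CoA;OAA	citrate	none
P42	2-oxoglutarate oxidoreductase (korABCD)	rTCA	K00176|K00177|K00178	succinate	2OG	none
P43	glutamine synthetase	anaplerotic	K01915	glutamate;ammonium	glutamine	none
P44	glutamate synthase (ferredoxin)	anaplerotic	K00264;K00284	glutamine;2OG	glutamate	none
P45	glutamate dehydrogenase	anaplerotic	K00261;K00262;K15371	2OG;ammonium	glutamate	none
P46	glutamate synthase (NADPH)	anaplerotic	K00265|K00266	glutamine;2OG	glutamate	none
P47	amidophosphoribosyltransferase (purF)	anaplerotic	K00764	glutamine		none
P48	isocitrate lyase	anaplerotic	K01637	citrate	succinate	none
P49	malate synthase	anaplerotic	K01638	acetyl-CoA	malate	none
P50	glyoxylate carboligase branch	anaplerotic	K01608		malate	none
P51	fatty-acid biosynthesis initiation (fabD/fabH/fabF)	fatty_acid	K00645|K00648|K09458|K00059|K02372|K00208	malonyl-CoA	fatty-acid	none
P52	methylmalonyl-CoA mutase/epimerase	3HP	K01847;K01848;K01849|K05606		succinate	none
P53	succinyl-CoA to fumarate/2-oxoglutarate	3HP	K01899|K01900	succinate	fumarate;2OG	none
P54	acetyl-CoA carboxylase	3HP	K01961;K11262|K01962|K01963|K02160	acetyl-CoA	malonyl-CoA	none
P55	malonyl-CoA reductase	3HP	K14468;K15039;K15052	malonyl-CoA		none
P56	exogenous fatty-acid activation and transfer	fatty_acid	K01897;K05939|K00631;K03621|K00655;K08591	fatty-acid		none
P57	ribulose-1,5-bisphosphate carboxylase (RuBisCO)	CBB	K01601|K01602			none
P58	phosphoribulokinase and RuBP regeneration	CBB	K00855|K01623;K01624|K00927|K00134|K01803|K01807|K00615|K01100|K01086		pyruvate	none
P59	acetate permease ActP	transport	K14393	acetate	acetate	import
P60	formate channel FocA	transport	K06212	formate;acetate	formate;acetate	bidirectional
P61	pyruvate uptake transporter	transport	K16323	pyruvate	pyruvate	import
P62	lactate permease LctP	transport	K03303	lactate	lactate	import
P63	fatty-acid efflux (AcrAB-TolC / FarE)	transport	K03585;K23595|K18138;K23595|K12340;K23595	fatty-acid	fatty-acid	export
P64	promiscuous dicarboxylate transporter DctA	transport	K11103	malate;succinate;fumarate	malate;succinate;fumarate	import
P65	TRAP dicarboxylate transporter DctPQM	transport	K11688|K11689|K11690	malate;succinate;fumarate	malate;succinate;fumarate	import
P66	glutamate/aspartate ABC transporter	transport	K10001|K10002|K10003|K10004	glutamate;aspartate	glutamate;aspartate	import
P67	glutamine ABC transporter GlnHPQ	transport	K10036|K10037|K10038	glutamine	glutamine	import
P68	serine transporter SstT	transport	K07862	serine	serine	import
P69	glycine transporter CycA	transport	K11737	glycine	glycine	import
P70	citrate-divalent cation symporter CitM	transport	K03300	citrate	citrate	import
P71	2-oxoglutarate permease KgtP	transport	K03761	2OG	2OG	import
P72	oxaloacetate uptake transporter	transport	K08177;K08178	OAA	OAA	import
P73	succinate exporter SucE	transport	K23326	succinate	succinate	export
P74	anaerobic C4-dicarboxylate antiporter DcuA	transport	K07791	malate;succinate;fumarate;aspartate	malate;succinate;fumarate;aspartate	bidirectional
P75	aspartate:alanine exchanger AspT	transport	K22278	aspartate	aspartate	import
P76	long-chain fatty-acid transporter FadL	transport	K06076	fatty-acid	fatty-acid	import
P77	C4-dicarboxylate antiporter DcuB	transport	K07792	fumarate;malate	fumarate;malate	bidirectional
P78	malate permease MaeN	transport	K16322	malate	malate	import
P79	acetate channel SatP	transport	K07034	acetate	acetate	bidirectional
P80	citrate ABC transporter TctABC	transport	K07793|K07794|K07795	citrate	citrate	import
P81	serine exporter	transport	K03297	serine	serine	export
P82	sodium-dependent succinate transporter SdcS	transport	K14445;K14446	succinate	succinate	import
P83	citrate exchanger CitT	transport	K09477	citrate	citrate	bidirectional
PN1	nitrate/nitrite ABC transporter NrtABCD	transport	K02575;K15576|K02598;K15577|K15578|K15579|K21990	nitrate;nitrite	nitrate;nitrite	import
PN2	dissimilatory nitrate reductase NarGH	nitrogen	K00370|K00371	nitrate	nitrite	none
PN3	dissimilatory nitrite reduction to ammonium NrfAH	nitrogen	K03385|K15876	nitrite	ammonium	none
PN4	assimilatory nitrate reductase NasAB	nitrogen	K00372|K00360	nitrate	nitrite	none
PN5	assimilatory nitrite reductase NirA	nitrogen	K00366	nitrite	ammonium	none
PN6	nitrogenase NifHDK	nitrogen	K02586|K02588|K02591	N2	ammonium	none
PN7	ammonium transporter/permease Amt	transport	K03320;K06580;K20989	ammonium	ammonium	import
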