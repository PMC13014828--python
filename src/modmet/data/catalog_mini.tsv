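module_id	name	pathway	ko_groups	substrates	products	direction
P8	glycine cleavage system (reductive direction)	rGly_Ser	K00281;K00282|K00605	formate	glycine	none
P9	serine hydroxymethyltransferase	rGly_Ser	K00600	glycine	serine	none
P12	D-lactate dehydrogenase	fermentation	K03778	pyruvate	lactate	none
P15	lactate utilization complex LldEFG	fermentation	K18928|K18929|K18930	lactate	pyruvate	none
P18	phosphate acetyltransferase	PAT_ACK	K00625	acetyl-CoA		none
P19	acetate kinase	PAT_ACK	K00925		acetate	none
P25	pyruvate synthase (ferredoxin)	rTCA	K03737	acetyl-CoA	pyruvate	none
P35	fumarate reductase	rTCA	K00244|K00245	fumarate	succinate	none
P37	2-oxoglutarate:ferredoxin oxidoreductase	rTCA	K00174|K00175	succinate	2OG	none
P40	ATP-citrate lyase	rTCA	K15230|K15231	citrate	acetyl-CoA;OAA	none
P42	2-oxoglutarate oxidoreductase korABCD	rTCA	K00176|K00177	succinate	2OG	none
P51	fatty-acid biosynthesis initiation	fatty_acid	K00645	malonyl-CoA	fatty-acid	none
P60	formate channel FocA	transport	K06212	formate;acetate	formate;acetate	bidirectional
P63	fatty-acid efflux	transport	K18138;K23595	fatty-acid	fatty-acid	export
P64	promiscuous dicarboxylate transporter DctA	transport	K11103	malate;succinate;fumarate	malate;succinate;fumarate	import
PN6	nitrogenase NifHDK	nitrogen	K02586|K02588|K02591	N2	ammonium	none
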