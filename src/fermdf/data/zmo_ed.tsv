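# organism: zmo
# Entner-Doudoroff route (via 6-phosphogluconate and KDPG) to pyruvate, then
# pyruvate decarboxylase and NADH-linked alcohol dehydrogenase (Z. mobilis,
# natural ethanologen).  One glucose yields one pyruvate + one g3p through the
# ED aldol cleavage; the lower-glycolysis reactions are written per reaction
# event.  Conventions: g3p = glyceraldehyde 3-phosphate; water omitted.
# cofactors: atp adp nad nadh nadp nadph pi
reaction_id	equation	pathway_position	kegg_ids
GLK	glc + atp = g6p + adp	1	glc=C00031;atp=C00002;g6p=C00092;adp=C00008
G6PDH	g6p + nadp = 6pgln + nadph	2	nadp=C00006;6pgln=C01236;nadph=C00005
PGL	6pgln = 6pgn	3	6pgn=C00345
EDD	6pgn = kdpg	4	kdpg=C04442
EDA	kdpg = pyr + g3p	5	pyr=C00022;g3p=C00118
GAP	g3p + nad + pi = bpg + nadh	6	nad=C00003;nadh=C00004;pi=C00009;bpg=C00236
PGK	bpg + adp = 3pg + atp	7	3pg=C00197
GPM	3pg = 2pg	8	2pg=C00631
ENO	2pg = pep	9	pep=C00074
PYK	pep + adp = pyr + atp	10
PDC	pyr = acald + co2	11	acald=C00084;co2=C00011
ADH	acald + nadh = etoh + nad	12	etoh=C00469
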