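# organism: eco
# Embden-Meyerhof-Parnas glycolysis plus the heterologous pyruvate-decarboxylase /
# NADH-linked alcohol-dehydrogenase route to ethanol (engineered E. coli ethanologen).
# Conventions: g3p = glyceraldehyde 3-phosphate; water is omitted from equations
# (activity 1); the triose branch is written as a single pass (coefficients per
# reaction event, not per glucose).
# cofactors: atp adp nad nadh pi coa
reaction_id	equation	pathway_position	kegg_ids
GLK	glc + atp = g6p + adp	1	glc=C00031;atp=C00002;g6p=C00092;adp=C00008
PGI	g6p = f6p	2	f6p=C00085
PFK	f6p + atp = fbp + adp	3	fbp=C00354
FBA	fbp = dhap + g3p	4	dhap=C00111;g3p=C00118
TPI	dhap = g3p	5
GAP	g3p + nad + pi = bpg + nadh	6	nad=C00003;nadh=C00004;pi=C00009;bpg=C00236
PGK	bpg + adp = 3pg + atp	7	3pg=C00197
GPM	3pg = 2pg	8	2pg=C00631
ENO	2pg = pep	9	pep=C00074
PYK	pep + adp = pyr + atp	10	pyr=C00022
PDC	pyr = acald + co2	11	acald=C00084;co2=C00011
ADH	acald + nadh = etoh + nad	12	etoh=C00469
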