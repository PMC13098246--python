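# organism: tsac
# Cellobiose phosphorolysis feeding EMP glycolysis, then the thermophile route
# to ethanol: pyruvate:ferredoxin oxidoreductase (PFOR), ferredoxin:NADP
# oxidoreduction (written with canonical FNORP stoichiometry; the organism
# carries reactions of equivalent net stoichiometry), acetyl-CoA reduction to
# acetaldehyde (ALDH) and NADPH-linked alcohol dehydrogenase (ADHP).
# Conventions: g3p = glyceraldehyde 3-phosphate; fdox/fdred denote the
# oxidized/reduced two-electron ferredoxin pool; water omitted (activity 1).
# cofactors: atp adp nad nadh nadp nadph pi coa fdox fdred
reaction_id	equation	pathway_position	kegg_ids
CBP	cb + pi = glc + g1p	1	cb=C00185;pi=C00009;glc=C00031;g1p=C00103
PGM	g1p = g6p	2	g6p=C00092
GLK	glc + atp = g6p + adp	3	atp=C00002;adp=C00008
PGI	g6p = f6p	4	f6p=C00085
PFK	f6p + atp = fbp + adp	5	fbp=C00354
FBA	fbp = dhap + g3p	6	dhap=C00111;g3p=C00118
TPI	dhap = g3p	7
GAP	g3p + nad + pi = bpg + nadh	8	nad=C00003;nadh=C00004;bpg=C00236
PGK	bpg + adp = 3pg + atp	9	3pg=C00197
GPM	3pg = 2pg	10	2pg=C00631
ENO	2pg = pep	11	pep=C00074
PYK	pep + adp = pyr + atp	12	pyr=C00022
PFOR	pyr + coa + fdox = accoa + co2 + fdred	13	coa=C00010;fdox=C00139;accoa=C00024;co2=C00011;fdred=C00138
FNORP	fdred + nadp = fdox + nadph	14	nadp=C00006;nadph=C00005
ALDH	accoa + nadh = acald + coa + nad	15	acald=C00084
ADHP	acald + nadph = etoh + nadp	16	etoh=C00469
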