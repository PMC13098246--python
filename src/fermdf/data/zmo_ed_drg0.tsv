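# temperature_k: 310.15
# provenance: curated approximate standard transformed Gibbs energies (kJ/mol) at
# provenance: pH 7.0, ionic strength 0.25 M, typical of component-contribution
# provenance: (eQuilibrator-style) estimates; values rounded to 0.5 kJ/mol.
reaction_id	drg0_kj_mol
GLK	-17.0
G6PDH	-3.0
PGL	-22.0
EDD	-15.0
EDA	16.0
GAP	7.0
PGK	-19.0
GPM	4.5
ENO	-4.0
PYK	-27.0
PDC	-17.0
ADH	-23.0
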