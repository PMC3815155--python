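# pH 7 protonation rule table: substructure pattern -> action on one atom.
# Columns (tab separated): rule_name, SMARTS, index of the target atom within
# the SMARTS match, action (protonate | deprotonate).
# Rules are matched simultaneously on the input molecule; the first rule to
# claim an atom wins.  Charge filters (+0) inside the patterns make every
# action idempotent: a group already in its pH 7 form is never matched again.
carboxylic_acid	[CX3](=[OX1])[OX2H1]	2	deprotonate
sulfonic_acid	[SX4](=[OX1])(=[OX1])[OX2H1]	3	deprotonate
phosphorus_oxyacid	[PX4](=[OX1])[OX2H1]	2	deprotonate
aliphatic_amine	[NX3;+0;!$([N]a);!$([N]=*);!$([N][CX3]=[OX1,SX1,#7]);!$([N][SX4](=[OX1])=[OX1]);!$([N][NX3]);!$([N][OX2]);!$([N]#*)]	0	protonate
amidine_guanidine	[NX2;+0]=[CX3]([NX3;+0])	0	protonate
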