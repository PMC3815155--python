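# Salt / counter-ion / solvent fragments removed before structure comparison.
# One SMILES per line (trailing comment allowed).  Both the neutral and the
# ionic form of each species are listed because sources disagree on which
# they store.  Matching ignores stereochemistry (e.g. any tartrate isomer).
[Cl-]	chloride
Cl	hydrogen chloride
[Br-]	bromide
Br	hydrogen bromide
[I-]	iodide
I	hydrogen iodide
[F-]	fluoride
F	hydrogen fluoride
[Na+]	sodium
[K+]	potassium
[Li+]	lithium
[Ca+2]	calcium
[Mg+2]	magnesium
[Zn+2]	zinc
[Ba+2]	barium
[Al+3]	aluminium
[NH4+]	ammonium
N	ammonia
O	water
OS(=O)(=O)O	sulfuric acid
OS(=O)(=O)[O-]	hydrogensulfate
[O-]S(=O)(=O)[O-]	sulfate
O[N+](=O)[O-]	nitric acid
[O-][N+](=O)[O-]	nitrate
OP(=O)(O)O	phosphoric acid
OP(=O)(O)[O-]	dihydrogenphosphate
OP(=O)([O-])[O-]	hydrogenphosphate
[O-]P(=O)([O-])[O-]	phosphate
CS(=O)(=O)O	methanesulfonic acid
CS(=O)(=O)[O-]	mesylate
OS(=O)(=O)c1ccccc1	benzenesulfonic acid
[O-]S(=O)(=O)c1ccccc1	besylate
Cc1ccc(S(=O)(=O)O)cc1	toluenesulfonic acid
Cc1ccc(S(=O)(=O)[O-])cc1	tosylate
CC(=O)O	acetic acid
CC(=O)[O-]	acetate
OC(=O)C(=O)O	oxalic acid
[O-]C(=O)C(=O)[O-]	oxalate
OC(=O)CCC(=O)O	succinic acid
[O-]C(=O)CCC(=O)[O-]	succinate
OC(=O)/C=C\C(=O)O	maleic acid
[O-]C(=O)/C=C\C(=O)[O-]	maleate
OC(=O)/C=C/C(=O)O	fumaric acid
[O-]C(=O)/C=C/C(=O)[O-]	fumarate
OC(=O)C(O)C(O)C(=O)O	tartaric acid
[O-]C(=O)C(O)C(O)C(=O)[O-]	tartrate
OC(=O)CC(O)(CC(=O)O)C(=O)O	citric acid
[O-]C(=O)CC(O)(CC(=O)[O-])C(=O)[O-]	citrate
OC(=O)c1ccccc1	benzoic acid
[O-]C(=O)c1ccccc1	benzoate
CO	methanol
CCO	ethanol
CC(C)O	isopropanol
CC(=O)C	acetone
CS(C)=O	dimethyl sulfoxide
C1CCOC1	tetrahydrofuran
CCOCC	diethyl ether
ClCCl	dichloromethane
ClC(Cl)Cl	chloroform
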