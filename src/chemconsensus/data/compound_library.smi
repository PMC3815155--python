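# Compound library for synthetic fixture worlds: drug-like molecules
# covering chiral, achiral, acidic, basic, zwitterionic and salt-formable cases.
# Format: SMILES<TAB>name
CC(=O)Oc1ccccc1C(=O)O	aspirin
CC(=O)Nc1ccc(O)cc1	paracetamol
CC(C)Cc1ccc(cc1)[C@@H](C)C(=O)O	ibuprofen
COc1ccc2cc(ccc2c1)[C@@H](C)C(=O)O	naproxen
Cn1cnc2c1c(=O)n(C)c(=O)n2C	caffeine
CN1CCC[C@H]1c1cccnc1	nicotine
CC(C)NCC(O)COc1ccc(CC(N)=O)cc1	atenolol
CC(C)NC[C@@H](O)COc1cccc2ccccc12	propranolol
COCCc1ccc(OCC(O)CNC(C)C)cc1	metoprolol
CC(C)(C)NCC(O)c1ccc(O)c(CO)c1	salbutamol
CN[C@@H](C)[C@H](O)c1ccccc1	ephedrine
CN[C@@H](C)[C@@H](O)c1ccccc1	pseudoephedrine
CC(N)Cc1ccccc1	amphetamine
CN[C@@H](C)Cc1ccccc1	methamphetamine
CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1	fluoxetine
CN[C@H]1CC[C@@H](c2ccc(Cl)c(Cl)c2)c2ccccc21	sertraline
CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1	diazepam
CN1CC[C@]23c4c5ccc(O)c4O[C@H]2[C@@H](O)C=C[C@H]3[C@H]1C5	morphine
CC(=O)C[C@@H](c1ccccc1)c1c(O)c2ccccc2oc1=O	warfarin
O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1	phenytoin
CCN(CC)CC(=O)Nc1c(C)cccc1C	lidocaine
CCN(CC)CCOC(=O)c1ccc(N)cc1	procaine
CCOC(=O)c1ccc(N)cc1	benzocaine
CCN(CC)CCC[C@@H](C)Nc1ccnc2cc(Cl)ccc12	chloroquine
COc1ccc2nccc([C@@H](O)[C@H]3C[C@@H]4CCN3C[C@@H]4C=C)c2c1	quinine
CN(C)C(=N)NC(N)=N	metformin
COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1	omeprazole
CNC(=C[N+](=O)[O-])NCCSCc1ccc(CN(C)C)o1	ranitidine
CC1=C(CSCCNC(=NC)NC#N)N=CN1	cimetidine
C[C@H](CS)C(=O)N1CCC[C@H]1C(=O)O	captopril
CCOC(=O)[C@H](CCc1ccccc1)N[C@@H](C)C(=O)N1CCC[C@H]1C(=O)O	enalapril
NCCCC[C@H](N[C@@H](CCc1ccccc1)C(=O)O)C(=O)N1CCC[C@H]1C(=O)O	lisinopril
CC1(C)S[C@@H]2[C@H](NC(=O)[C@H](N)c3ccc(O)cc3)C(=O)N2[C@H]1C(=O)O	amoxicillin
CC1(C)S[C@@H]2[C@H](NC(=O)Cc3ccccc3)C(=O)N2[C@H]1C(=O)O	benzylpenicillin
CC1=C(C(=O)O)N2C(=O)[C@@H](NC(=O)[C@H](N)c3ccccc3)[C@H]2SC1	cephalexin
Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1	sulfamethoxazole
COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC	trimethoprim
O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O	ciprofloxacin
CCn1cc(C(=O)O)c(=O)c2cc(F)c(N3CCNCC3)cc21	norfloxacin
NNC(=O)c1ccncc1	isoniazid
NC(=O)c1cnccn1	pyrazinamide
CC[C@@H](CO)NCCN[C@@H](CC)CO	ethambutol
Nc1ccc(cc1)S(=O)(=O)c1ccc(N)cc1	dapsone
Cc1ncc([N+](=O)[O-])n1CCO	metronidazole
OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F	fluconazole
Nc1nc2n(COCCO)cnc2c(=O)[nH]1	acyclovir
Cc1cn([C@H]2C[C@H](N=[N+]=[N-])[C@@H](CO)O2)c(=O)[nH]c1=O	zidovudine
Nc1ccn([C@@H]2CS[C@H](CO)O2)c(=O)n1	lamivudine
N[C@@H](Cc1ccc(O)c(O)c1)C(=O)O	levodopa
C[C@](N)(Cc1ccc(O)c(O)c1)C(=O)O	methyldopa
NCC1(CC(=O)O)CCCCC1	gabapentin
CC(C)C[C@H](CN)CC(=O)O	pregabalin
NC[C@H](CC(=O)O)c1ccc(Cl)cc1	baclofen
CN(C)C[C@H]1CCCC[C@]1(O)c1cccc(OC)c1	tramadol
CNC1(c2ccccc2Cl)CCCCC1=O	ketamine
NCCc1ccc(O)c(O)c1	dopamine
NCCc1c[nH]c2ccc(O)cc12	serotonin
NCCc1c[nH]cn1	histamine
CNC[C@H](O)c1ccc(O)c(O)c1	adrenaline
CC(C)NCC(O)c1ccc(O)c(O)c1	isoprenaline
Cn1c(=O)c2[nH]cnc2n(C)c1=O	theophylline
CCC1(c2ccccc2)C(=O)NC(=O)NC1=O	phenobarbital
CCC1(c2ccccc2)C(=O)NCNC1=O	primidone
CCCC(CCC)C(=O)O	valproic_acid
NC(=O)N1c2ccccc2C=Cc2ccccc21	carbamazepine
NC(=O)N1c2ccccc2CC(=O)c2ccccc21	oxcarbazepine
Nc1nnc(-c2cccc(Cl)c2Cl)c(N)n1	lamotrigine
O=c1[nH]cnc2[nH]ncc12	allopurinol
NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O	hydrochlorothiazide
NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl	furosemide
NC(=N)NC(=O)c1nc(Cl)c(N)nc1N	amiloride
COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]	nifedipine
CCOC(=O)C1=C(COCCN)NC(C)=C(C(=O)OC)[C@@H]1c1ccccc1Cl	amlodipine
COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC	verapamil
CN(C)CCN1c2ccccc2S[C@@H](c2ccc(OC)cc2)[C@@H](OC(C)=O)C1=O	diltiazem
CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1	losartan
Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1	celecoxib
OC(=O)COCCN1CCN(C(c2ccccc2)c2ccc(Cl)cc2)CC1	cetirizine
CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc32)CC1	loratadine
CN(C)CCOC(c1ccccc1)c1ccccc1	diphenhydramine
CN(C)CC[C@@H](c1ccc(Cl)cc1)c1ccccn1	chlorpheniramine
OC1(CCN(CCCC(=O)c2ccc(F)cc2)CC1)c1ccc(Cl)cc1	haloperidol
OCCOCCN1CCN(CC1)C1=Nc2ccccc2Sc2ccccc21	quetiapine
CN(C)CCC[C@]1(c2ccc(F)cc2)OCc2cc(C#N)ccc21	citalopram
CN(C)CC(c1ccc(OC)cc1)C1(O)CCCCC1	venlafaxine
CC(NC(C)(C)C)C(=O)c1cccc(Cl)c1	bupropion
CC/C(=C(\c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1	tamoxifen
OC(=O)CCCc1ccc(N(CCCl)CCCl)cc1	chlorambucil
O=P1(N(CCCl)CCCl)NCCCO1	cyclophosphamide
O=c1[nH]cc(F)c(=O)[nH]1	fluorouracil
Sc1ncnc2[nH]cnc12	mercaptopurine
C[C@]12CC[C@H]3[C@@H](CCC4=CC(=O)CC[C@]34C)[C@@H]1CC[C@@H]2O	testosterone
C[C@]12CC[C@H]3c4ccc(O)cc4CC[C@H]3[C@@H]1CC[C@@H]2O	estradiol
Cc1cccc(Nc2ccccc2C(=O)O)c1C	mefenamic_acid
OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl	diclofenac
COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1	indomethacin
CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1	ketoprofen
CCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1	tolbutamide
CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21	chlorpromazine
CC(CN1c2ccccc2Sc2ccccc21)N(C)C	promethazine
CN(C)CCCN1c2ccccc2CCc2ccccc21	imipramine
CN(C)CCC=C1c2ccccc2CCc2ccccc21	amitriptyline
CNCCC=C1c2ccccc2CCc2ccccc21	nortriptyline
Clc1cccc(Cl)c1NC1=NCCN1	clonidine
OC[C@@H](NC(=O)C(Cl)Cl)[C@H](O)c1ccc([N+](=O)[O-])cc1	chloramphenicol
O=C1CN(/N=C/c2ccc([N+](=O)[O-])o2)C(=O)N1	nitrofurantoin
COC(=O)Nc1nc2ccc(C(=O)c3ccccc3)cc2[nH]1	mebendazole
CCCSc1ccc2[nH]c(NC(=O)OC)nc2c1	albendazole
O=C(C1CCCCC1)N1C[C@H]2N(CCc3ccccc32)C(=O)C1	praziquantel
Nc1nc2ncc(CNc3ccc(C(=O)N[C@@H](CCC(=O)O)C(=O)O)cc3)nc2c(=O)[nH]1	folic_acid
OC[C@H](O)[C@H]1OC(=O)C(O)=C1O	ascorbic_acid
Cc1ncc(CO)c(CO)c1O	pyridoxine
OC(=O)c1cccnc1	niacin
CNC[C@H](O)c1cccc(O)c1	phenylephrine
CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1	fentanyl
CCOC(=O)C1(c2ccccc2)CCN(C)CC1	pethidine
CCC(=O)C(CC(C)N(C)C)(c1ccccc1)c1ccccc1	methadone
CNS(=O)(=O)Cc1ccc2[nH]cc(CCN(C)C)c2c1	sumatriptan
COc1ccc2[nH]cc(CCNC(C)=O)c2c1	melatonin
NCCS(=O)(=O)O	taurine
NCC(=O)O	glycine
CN1CCc2cccc3c2[C@H]1Cc1ccc(O)c(O)c1-3	apomorphine
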