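# ChemSpider-like reference+structural source for the packaged worked example.
# Queried by "Apomorphine Hydrochloride" it returns four structural IDs: its
# own matching record plus three cross-references, one of which is the
# PubChem record — so that ID accumulates 1 + 1/4 = 1.25 votes.  All four
# records are formulation variants (free base, salt, hemihydrate) that
# standardize to the same API structure.
roles: reference structural

record: 10302
smiles: CN1CCc2cccc3c2[C@H]1Cc1ccc(O)c(O)c1-3.Cl
name: Apomorphine hydrochloride
synonym: Apomorphine
xref: pubchem 107882
xref: chemspider 96602
xref: chemspider 157862

record: 96602
smiles: CN1CCc2cccc3c2[C@H]1Cc1ccc(O)c(O)c1-3
name: Apomorphine
synonym: Apomorphinum

record: 157862
smiles: CN1CCc2cccc3c2[C@H]1Cc1ccc(O)c(O)c1-3.O
name: Apomorphine hemihydrate
synonym: Apomorphine
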