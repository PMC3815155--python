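# PubChem-like reference+structural source for the packaged worked example.
# Queried by "Apomorphine Hydrochloride" it returns exactly one structural ID
# (its own record), stored as an SDF V2000 molfile of the hydrochloride salt.
roles: reference structural

record: 107882
molfile: 107882.mol
name: Apomorphine hydrochloride
synonym: Apomorphine
synonym: Apomorphine HCl
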