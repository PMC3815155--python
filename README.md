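# chemconsensus

Consensus curation of drug and chemical structures across conflicting
record sources.

## The problem

Public chemical databases disagree. Query several well-used databases for
the same drug name and you will occasionally get back structures that differ
in the configuration of a single chiral center — or, worse, in connectivity
or substituents. For structure-based work (virtual screening, repurposing
campaigns) a single flipped stereocenter can move a ligand from the top of a
docking ranking to the bottom, so a curated, single-structure-per-drug
database is a prerequisite, not a nicety.

`chemconsensus` resolves a drug/chemical *name* to a single standardized
structure by a fractional rank-by-vote scheme over any number of
chemical-record sources, then assembles the winners into a merged, curated
database and profiles its drug-likeness.

## The algorithm

For a query name, every **reference source** is polled and returns a list of
structural-database IDs (its own record and/or cross-references). A source
returning *k* IDs contributes a vote of **1/k to each ID**, so every
responsive source carries total weight 1. Each voted ID is fetched from its
**structural source** and standardized:

1. strip counter-ions and solvents, keep the active pharmaceutical
   ingredient (API) fragment;
2. set the pH 7 protonation state by a deterministic rule table
   (carboxylic/sulfonic acids deprotonated, aliphatic amines and
   amidines/guanidines protonated, phenols/amides untouched);
3. apply one fixed aromaticity model and emit a **canonical isomeric
   SMILES**, the structure-equality key.

Votes of IDs that collapse onto the same canonical SMILES add. The outcome
for a name is one of:

| status        | meaning                                                        |
|---------------|----------------------------------------------------------------|
| `consensus`   | every candidate standardizes to one structure                  |
| `majority`    | one structure's vote strictly exceeds every other              |
| `no_majority` | tie at the top — flagged for manual review, never guessed      |
| `not_found`   | no source returned any ID                                      |

Votes are exact rationals (`fractions.Fraction`): with denominators like 3
and 7 in play, float arithmetic cannot reliably distinguish a genuine tie
from rounding noise, and ties change the outcome class.

Entries that share a standardized structure (salt forms, brand names) are
merged into one record carrying the union of cross-references and the
frequency-sorted synonym list.

## Worked example

The packaged fixture reproduces a classic two-source situation: a
PubChem-like source answers "Apomorphine Hydrochloride" with a single ID,
while a ChemSpider-like source answers with four IDs — one of which is the
same PubChem record, the others being formulation variants (free base,
salt, hemihydrate) of the same API.

```bash
chemconsensus resolve "Apomorphine Hydrochloride"
```

prints (abridged):

```json
{
  "name": "Apomorphine Hydrochloride",
  "status": "consensus",
  "winner_smiles": "C[NH+]1CCc2cccc3c2[C@H]1Cc1ccc(O)c(O)c1-3",
  "ranked_ids": [
    {"source": "pubchem", "id": "107882", "vote": "5/4", "vote_decimal": 1.25},
    {"source": "chemspider", "id": "10302", "vote": "1/4", "vote_decimal": 0.25}
  ]
}
```

The shared ID earns 1 vote for being the only PubChem result plus 1/4 for
being one of ChemSpider's four IDs — 1.25 total — and because all four
records standardize to the same protonated apomorphine structure the outcome
is a full consensus.

A synthetic end-to-end run (30 compounds, 5 sources, 20% per-source
corruption):

```bash
chemconsensus make-world demo_world --seed 5 --compounds 30 --corruption 0.2
chemconsensus curate names.txt --world demo_world --out-prefix curated
```

```json
{
  "n_names": 30,
  "n_entries": 28,
  "counts": {"consensus": 7, "majority": 21, "no_majority": 2, "not_found": 0},
  "percentages": {"consensus": 23.33, "majority": 70.0, "no_majority": 6.67,
                  "not_found": 0.0}
}
```

Most names survive a 20% corruption rate because a wrong structure must
out-vote the agreeing clean sources; the two flagged names hit exact ties
and go to manual review rather than being guessed.

## Drug-likeness profiling

`chemconsensus profile set.smi` (or `.sdf`) computes molecular weight,
rotatable bonds, and Lipinski H-bond donor/acceptor counts per compound plus
the Rule-of-5 pass rate (≤ 1 violation; computed logP deliberately omitted).
`chemconsensus compare a.smi b.smi -p mw` runs a Pearson chi-squared test of
two sets' binned property distributions, pooling sparse bins.

## Layout

- `src/chemconsensus/sources.py` — source contract, plain-text fixture
  worlds, registry
- `src/chemconsensus/standardize.py` — salt stripping, pH 7 protonation,
  canonical isomeric SMILES
- `src/chemconsensus/consensus.py` — fractional vote tallying and outcome
  classification
- `src/chemconsensus/assemble.py` — entry assembly, synonym collection,
  duplicate merging, writers
- `src/chemconsensus/profile.py` — descriptors, Rule-of-5, chi-squared
  comparison
- `src/chemconsensus/synthesize.py` — synthetic corrupted worlds with known
  ground truth
- `docs/methods.md` — modelling assumptions, parameter defaults, known
  limitations
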