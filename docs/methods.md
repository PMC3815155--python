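# Methods

## The consensus model

The toolkit treats structure curation as a voting problem. Each *reference
source* polled by a compound name is one voter with total weight 1; a source
answering with *k* structural-database IDs splits its weight as 1/k per ID.
This makes a source that emits many cross-references no more influential
than one that emits a single confident pointer. After standardization, the
votes of all IDs that resolve to the same canonical isomeric SMILES are
summed, and the name is classified:

- **consensus** — exactly one distinct standardized structure among all
  candidates;
- **majority** — several distinct structures, one of which has a strictly
  larger summed vote than every other;
- **no_majority** — the top vote is tied (or no candidate could be
  standardized). The name is flagged for manual review; the tool never
  breaks a tie by an arbitrary rule, because a silently guessed structure
  would contaminate the output database in exactly the way the voting scheme
  exists to prevent;
- **not_found** — no source knows the name.

Votes are exact rationals throughout. With five sources the attainable vote
values have denominators up to the number of IDs a source returns, and
whether two structures are *exactly* tied decides the outcome class — float
accumulation would make that decision depend on summation order.

Two further rules:

- **Forfeiture.** An ID whose structure cannot be fetched or standardized
  forfeits its votes, but the ID and its lost mass stay in the per-name
  report. Dropping them silently would hide source decay; redistributing
  them would let a broken record change the relative weights of working
  ones.
- **Duplicate sources.** Two hits claiming the same reference source are an
  error, not a merge: it would double-weight that source.

Name matching in sources is case-insensitive, collapses whitespace runs and
strips surrounding punctuation, and is deliberately not fuzzy: an
edit-distance match could silently redirect vote mass to a different
compound.

## Standardization

Raw records (SDF V2000 molfile blocks or SMILES) pass through three stages:

1. **API extraction.** Multi-fragment records are reduced by removing every
   fragment on a shipped, editable exclusion list (halides, alkali and
   alkaline-earth ions, ammonium, sulfate/nitrate/phosphate, mesylate,
   tosylate, besylate, common carboxylate counter-ions, water, common
   solvents — each in both neutral and ionic form; matching ignores
   stereochemistry so any tartrate isomer is recognized). Of the remaining
   fragments the one with the most heavy atoms is kept. An exact tie between
   structurally different fragments keeps all tied fragments and flags the
   record as a potential co-crystal/multi-API case. A single-fragment record
   is always kept as-is, even if the same species appears on the exclusion
   list (ethanol the solvent vs. ethanol the compound). Pure-salt records
   (e.g. lone sodium chloride) raise a distinct no-API signal. Fragment
   selection depends only on fragment content, never on input order.
2. **pH 7 protonation.** A rule table (shipped as data,
   `data/protonation_rules.tsv`) maps substructure patterns to protonate/
   deprotonate actions: carboxylic, sulfonic and phosphorus oxyacids are
   deprotonated; aliphatic amines (primary through tertiary, excluding
   anilines, amides, sulfonamides, and any nitrogen on a carbon
   double-bonded to O/S/N) and amidine/guanidine imino nitrogens are
   protonated. All patterns are matched against the input simultaneously and
   the first rule to claim an atom wins, so the result is independent of
   rule order. Every pattern requires the neutral form, which makes the
   operation idempotent — and convergent from both directions: a source
   storing the neutral amine and a source storing the ammonium salt end up
   on the same form. This is a deterministic rule table, not a pKa
   predictor; borderline groups (tetrazoles, biguanides) follow the table's
   simplifications consistently across all sources, which is what the
   comparison needs.
3. **Canonicalization.** RDKit's default sanitization supplies the single
   aromaticity model (kekulized and aromatic inputs converge), stereo flags
   are re-perceived from what the input defines, and the canonical isomeric
   SMILES is emitted. Undefined stereocenters stay undefined — the tool
   never invents configuration, so a fully specified and an unspecified form
   of the same scaffold are *different* candidates and will surface as a
   vote disagreement. Tautomers are likewise not canonicalized; differing
   tautomers remain distinct structures.

Standardization is idempotent (re-standardizing its output returns the same
string), invariant under atom reordering and input format (molfile vs
SMILES), and collapses all salt forms of one API to one key. These four
properties are what the voting layer assumes, and all four are enforced by
tests over the packaged 122-compound library.

## Synthetic worlds

`synthesize.build_world` generates fixture worlds with known ground truth.
Per compound and reference source, an independent coin with probability
`corruption_prob` decides whether that source's record is corrupted;
otherwise the record stores the true structure under a randomly chosen
convention (canonical SMILES, kekulized SMILES, or the pH-7 protonated
form), decorated with a counter-ion/solvate partner with probability
`salt_form_prob` (default 0.3).

Corruption modes and default weights follow the error taxonomy observed
across public databases — stereochemistry discrepancies dominate, with
rarer substituent and connectivity errors:

| mode                  | weight | operation                                        |
|-----------------------|--------|--------------------------------------------------|
| `stereo_flip`         | 0.6    | invert one defined tetrahedral center            |
| `substituent_swap`    | 0.25   | swap one terminal substituent from a fixed table (N↔O, F↔Cl, Br→Cl, I→Br, S→O, C→N, carbonyl O↔S, or replace an H with methyl) |
| `connectivity_change` | 0.15   | detach one terminal atom and reattach it elsewhere |

Every corruption is *effective*: it is resampled until its standardized form
differs from the truth and from every other corruption of the same compound
(chaining two or three operations when a small rigid molecule cannot supply
enough distinct single-edit errors). `corruption_prob` is therefore exactly
the probability that a source's vote lands on a wrong, distinct structure,
which gives the recovery rate a closed form: with *s* sources and all-wrong
votes distinct, the truth wins iff at least two sources are clean, i.e.
P(recover) = P(Binomial(s, 1−p) ≥ 2). One clean source only *ties* the
singleton wrong votes, and ties go to manual review by design. The recovery
acceptance test checks the simulated rate against this expression at
s = 5, p ∈ {0.1, 0.3} with 2,000 replicates per condition (a problem size
chosen to put three binomial standard errors near half a percentage point).

What the generator does **not** emulate: real databases' correlated errors
(two databases mirroring each other's mistake), name collisions (one brand
name meaning different compounds regionally), record-level missingness
patterns, and realistic synonym vocabularies. Passing the recovery test
therefore validates the voting arithmetic under independent errors, not the
error structure of any particular public database.

A generated world can be written to disk in the same plain-text fixture
format the loader reads; the same seed yields a byte-identical directory.

## Drug-likeness profiling

Descriptors use Lipinski's operational definitions so every count is
auditable by hand: HBD = number of O–H and N–H hydrogens; HBA = number of N
and O atoms excluding pyrrole-type aromatic nitrogens and amide nitrogens;
rotatable bonds follow RDKit's strict rotor convention (non-ring single
bonds between non-terminal heavy atoms; amide — and also ester and
amidine — bonds excluded). Rule-of-5 violations are counted over MW ≤ 500,
HBD ≤ 5, HBA ≤ 10; computed logP is excluded from the profile because logP
prediction is too unreliable to gate on, so violation counts range 0–3 and
"passes with ≤ 1 violation" is judged on the three computable rules.

Group comparison bins one property into equal-width bins (defaults:
MW 50 g/mol up to 700 with an overflow bin; unit bins for the three counts)
and applies the plain Pearson chi-squared statistic to the 2×k table, with
no continuity correction. Adjacent bins are pooled left-to-right until every
pooled bin's minimum expected count reaches 5 (a trailing sparse bin folds
into its left neighbour); degenerate tables (a single surviving row or
column) return statistic 0, p = 1. The test's type-I error at α = 0.05 is
verified by simulation to sit within three standard errors of nominal.

## Numerical and design choices

- Ranking ties among IDs break lexicographically by (source, id) — purely
  for reproducible output; ID rank never decides an outcome, structure-level
  votes do.
- The vote denominator is the total number of IDs a source returns across
  all namespaces, not per-namespace; a source's own record (when it has a
  structural role) counts among its returned IDs alongside cross-references.
- Merged entries take the most frequent synonym as the display name (query
  names are often salt-qualified — "X hydrochloride" — while the merged
  record represents the API); the fallback is the lexicographically first
  input name. Output is sorted by canonical SMILES so runs diff cleanly.
- A source that errors during a run contributes zero vote mass and is listed
  in the run report as non-responsive; the run never aborts on one bad
  source.
- Live web-service adapters exist only as a contract (`CallableSource`);
  nothing in the package or tests performs network access.

## Known limitations

- The protonation table is intentionally small; unusual ionizable groups
  (tetrazoles, N-oxides, phosphonium species) pass through unchanged.
  Consistency across sources, not physiological accuracy, is the design
  goal.
- Tautomer and undefined-stereo disagreements are surfaced as vote
  conflicts rather than silently normalized; worlds rich in such variants
  will show more `majority`/`no_majority` outcomes.
- Multi-API (co-crystal) records are kept and flagged but downstream
  profiling requires single fragments.
- The closed-form recovery analysis assumes independent corruption across
  sources; correlated errors would lower recovery below the formula.
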