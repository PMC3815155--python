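"""Structure standardization: raw record -> comparable canonical form.

Chemical-record sources disagree on how they draw the same drug: different
salt forms, protonation states, kekulization and atom ordering.  Before any
two records can be compared, each is reduced to its active pharmaceutical
ingredient (API) and normalized:

1. ``strip_to_api``   — drop counter-ions/solvents, keep the API fragment;
2. ``protonate_ph7``  — apply a deterministic pH 7 protonation rule table;
3. ``canonicalize``   — one aromaticity model, canonical isomeric SMILES.

The composition of the three is :func:`standardize`.  The canonical isomeric
SMILES string is the structure-equality key for the whole pipeline: two
records denote the same structure iff their standardized strings are equal.
Stereochemistry present in the input is preserved exactly; undefined
stereocenters are never assigned, so a specified and an unspecified form of
the same scaffold remain distinct candidates.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem, RDLogger
from rdkit.Chem import rdMolDescriptors

from .errors import NoApiFragmentError, StandardizationError, StructureParseError

RDLogger.DisableLog("rdApp.*")

DATA_DIR = Path(__file__).resolve().parent / "data"

# property set on a molecule when API selection kept >1 equally large fragment
MULTI_API_FLAG = "multiApiTie"


@dataclass(frozen=True)
class StandardizedStructure:
    """A salt-stripped, pH-7-protonated, canonical isomeric SMILES structure.

    ``provenance`` lists the (source_name, record_id) pairs whose raw records
    collapsed onto this canonical form.
    """

    canonical_smiles: str
    parent_formula: str
    stereocenters_defined: int
    stereocenters_total: int
    provenance: tuple[tuple[str, str], ...] = field(default_factory=tuple)
    multi_api: bool = False

    def with_provenance(self, provenance) -> "StandardizedStructure":
        return StandardizedStructure(
            self.canonical_smiles, self.parent_formula,
            self.stereocenters_defined, self.stereocenters_total,
            tuple(provenance), self.multi_api)


# ---------------------------------------------------------------------------
# parsing

def parse_structure(raw: str) -> Chem.Mol:
    """Parse a raw structure string (SDF/V2000 molfile block or SMILES).

    Raises :class:`StructureParseError` on empty or unparseable input.
    """
    if raw is None or not raw.strip():
        raise StructureParseError("empty structure")
    if "\n" in raw or "V2000" in raw or "V3000" in raw:
        mol = Chem.MolFromMolBlock(raw, sanitize=True, removeHs=True)
    else:
        mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise StructureParseError(f"unparseable structure: {raw[:60]!r}")
    return mol


def _as_mol(structure) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    return parse_structure(structure)


# ---------------------------------------------------------------------------
# salt / solvent stripping

@functools.lru_cache(maxsize=1)
def _exclusion_smiles() -> frozenset[str]:
    """Canonical stereo-stripped SMILES of all excluded fragments."""
    out = set()
    path = DATA_DIR / "salt_exclusions.smi"
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smi = line.split("\t")[0].split()[0]
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - guarded by tests on the data file
            raise ValueError(f"bad exclusion-list SMILES: {smi!r}")
        Chem.RemoveStereochemistry(mol)
        out.add(Chem.MolToSmiles(mol))
    return frozenset(out)


def _fragment_key(frag: Chem.Mol) -> str:
    """Stereo-stripped canonical SMILES used for exclusion-list membership."""
    copy = Chem.Mol(frag)
    Chem.RemoveStereochemistry(copy)
    return Chem.MolToSmiles(copy)


def is_excluded_fragment(frag: Chem.Mol) -> bool:
    return _fragment_key(frag) in _exclusion_smiles()


def strip_to_api(structure) -> Chem.Mol:
    """Return the API fragment(s) of a possibly multi-fragment structure.

    Fragments on the exclusion list are removed; of the remainder, the
    fragment with the most heavy atoms is kept.  An exact tie between
    structurally different fragments keeps all tied fragments (a co-crystal
    API) and flags the result; identical duplicates collapse to one copy.
    The choice depends only on fragment content, never on input order.
    """
    mol = _as_mol(structure)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        # a single-fragment record IS the compound, even if the same species
        # appears on the exclusion list as somebody else's solvate partner
        return frags[0]
    kept = [f for f in frags if not is_excluded_fragment(f)]
    if not kept:
        raise NoApiFragmentError(
            "all fragments are on the salt/solvent exclusion list")
    # order-independent ranking: heavy-atom count, then canonical SMILES
    ranked = sorted(kept, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    top_count = ranked[0].GetNumHeavyAtoms()
    top = [f for f in ranked if f.GetNumHeavyAtoms() == top_count]
    distinct: dict[str, Chem.Mol] = {}
    for f in top:
        distinct.setdefault(Chem.MolToSmiles(f), f)
    frag_list = [distinct[s] for s in sorted(distinct)]
    api = frag_list[0]
    for extra in frag_list[1:]:
        api = Chem.CombineMols(api, extra)
    if len(frag_list) > 1:
        api.SetBoolProp(MULTI_API_FLAG, True)
    return api


# ---------------------------------------------------------------------------
# pH 7 protonation

@dataclass(frozen=True)
class ProtonationRule:
    name: str
    smarts: str
    atom_position: int
    action: str  # "protonate" | "deprotonate"

    @property
    def pattern(self) -> Chem.Mol:
        return _compile_smarts(self.smarts)


@functools.lru_cache(maxsize=64)
def _compile_smarts(smarts: str) -> Chem.Mol:
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:  # pragma: no cover
        raise ValueError(f"bad SMARTS in protonation rule table: {smarts!r}")
    return patt


@functools.lru_cache(maxsize=1)
def load_protonation_rules() -> tuple[ProtonationRule, ...]:
    rules = []
    path = DATA_DIR / "protonation_rules.tsv"
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts, pos, action = line.split("\t")
        if action not in ("protonate", "deprotonate"):  # pragma: no cover
            raise ValueError(f"unknown action {action!r} in rule {name!r}")
        rules.append(ProtonationRule(name, smarts, int(pos), action))
    return tuple(rules)


def protonate_ph7(structure) -> Chem.Mol:
    """Set the pH 7 protonation state via the shipped rule table.

    All rules are matched against the *input* molecule simultaneously and the
    first rule to claim an atom wins, so the outcome is independent of rule
    application order.  Idempotent: each pattern requires the neutral form.
    """
    mol = Chem.Mol(_as_mol(structure))
    actions: dict[int, str] = {}
    for rule in load_protonation_rules():
        for match in mol.GetSubstructMatches(rule.pattern):
            idx = match[rule.atom_position]
            actions.setdefault(idx, rule.action)
    if not actions:
        return mol
    rw = Chem.RWMol(mol)
    for idx, action in actions.items():
        atom = rw.GetAtomWithIdx(idx)
        n_h = atom.GetTotalNumHs()
        if action == "deprotonate":
            if n_h < 1:
                continue
            atom.SetFormalCharge(atom.GetFormalCharge() - 1)
            atom.SetNumExplicitHs(n_h - 1)
        else:
            atom.SetFormalCharge(atom.GetFormalCharge() + 1)
            atom.SetNumExplicitHs(n_h + 1)
        atom.SetNoImplicit(True)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:  # valence violation from a bad rule application
        raise StandardizationError(f"protonation produced invalid molecule: {exc}")
    return out


# ---------------------------------------------------------------------------
# canonicalization

def canonicalize(structure, provenance=()) -> StandardizedStructure:
    """Emit the canonical isomeric SMILES under one fixed aromaticity model.

    Uses RDKit's default (RDKit-aromaticity) sanitization so kekulized and
    aromatic inputs converge, reassigns stereo flags from what the input
    defines (never inventing configuration for undefined centers), and
    canonicalizes atom order.
    """
    mol = Chem.Mol(_as_mol(structure))
    multi = mol.HasProp(MULTI_API_FLAG) if mol.GetNumAtoms() else False
    try:
        Chem.SanitizeMol(mol)
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        smiles = Chem.MolToSmiles(mol)
        back = Chem.MolFromSmiles(smiles)
        if back is None:
            raise StandardizationError("canonical SMILES failed round-trip",
                                       provenance)
    except StandardizationError:
        raise
    except Exception as exc:
        raise StandardizationError(str(exc), provenance)
    centers = Chem.FindMolChiralCenters(back, includeUnassigned=True,
                                        useLegacyImplementation=False)
    defined = sum(1 for _, tag in centers if tag not in ("?",))
    return StandardizedStructure(
        canonical_smiles=smiles,
        parent_formula=rdMolDescriptors.CalcMolFormula(back),
        stereocenters_defined=defined,
        stereocenters_total=len(centers),
        provenance=tuple(provenance),
        multi_api=multi,
    )


# ---------------------------------------------------------------------------
# composed pipeline

@functools.lru_cache(maxsize=16384)
def _standardize_core(raw: str) -> StandardizedStructure:
    mol = parse_structure(raw)
    api = strip_to_api(mol)
    api = protonate_ph7(api)
    return canonicalize(api)


def standardize(raw_structure, provenance=()) -> StandardizedStructure:
    """Full standardization: strip salts, set pH 7 protonation, canonicalize.

    ``provenance`` is a sequence of (source_name, record_id) pairs recorded on
    the result.  Raises :class:`StructureParseError`,
    :class:`NoApiFragmentError` or :class:`StandardizationError`.
    """
    if isinstance(raw_structure, Chem.Mol):
        raw_structure = Chem.MolToSmiles(raw_structure)
    return _standardize_core(raw_structure).with_provenance(provenance)


def canonical_smiles(raw_structure) -> str:
    """Shorthand: the canonical standardized SMILES of a raw structure."""
    return standardize(raw_structure).canonical_smiles
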