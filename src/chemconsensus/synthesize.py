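"""Synthetic multi-database worlds with known ground truth.

The generator emulates the situation a name-to-structure curation run
confronts: several reference databases answer a compound name with pointers
into structural databases, most of which store the same molecule under
different conventions (salt forms, protonation states, kekulized vs aromatic
SMILES), while a minority store a genuinely wrong structure.  Corruption
modes mirror the error taxonomy seen across public chemical databases:
flipped stereocenters (the most common discrepancy), wrong substituents, and
wrong connectivity.

Corruptions are *effective* by construction: a corrupted record is resampled
until its standardized form differs from the truth and from every other
corruption of the same compound, so ``corruption_prob`` is exactly the
probability that a source's vote lands on a wrong, distinct structure.  That
makes the ground-truth recovery probability a closed-form quantity: with
``s`` sources voting and every wrong vote on its own structure, the truth
wins iff at least two sources are clean (one clean source merely ties the
singleton wrong votes, and ties go to manual review).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .errors import ChemConsensusError, CorruptionNotApplicableError
from .sources import FixtureSource, SourceRecord, SourceRegistry
from .standardize import DATA_DIR, standardize

#: counter-ion / solvate partners used to decorate clean records (neutral
#: forms, so no charge balancing is needed)
SALT_PARTNERS = ("Cl", "Br", "O", "OS(=O)(=O)O", "CS(=O)(=O)O",
                 "OC(=O)/C=C\\C(=O)O")
SALT_SUFFIX = {"Cl": "hydrochloride", "Br": "hydrobromide", "O": "hydrate",
               "OS(=O)(=O)O": "sulfate", "CS(=O)(=O)O": "mesylate",
               "OC(=O)/C=C\\C(=O)O": "maleate"}

CORRUPTION_MODES = ("stereo_flip", "substituent_swap", "connectivity_change")

#: terminal-atom element swaps guaranteed to stay valence-legal
_SWAP_TABLE = {7: 8, 8: 7, 9: 17, 17: 9, 35: 17, 53: 35, 16: 8, 6: 7}
#: swaps for terminal atoms attached by a double bond (carbonyl <-> thiocarbonyl)
_DOUBLE_SWAP_TABLE = {8: 16, 16: 8}
#: sentinel: replace one hydrogen substituent with a methyl group
_METHYLATE = -1


@functools.lru_cache(maxsize=1)
def load_compound_library() -> tuple[tuple[str, str], ...]:
    """The packaged (name, SMILES) drug-like compound library."""
    out = []
    for line in (DATA_DIR / "compound_library.smi").read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, name = line.split("\t")
        out.append((name, smiles))
    return tuple(out)


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of one synthetic world.

    ``corruption_prob`` is the per-(reference source, compound) probability
    that the record the source's vote resolves to is an effective corruption.
    """

    n_compounds: int = 50
    n_reference_sources: int = 5
    n_structural_sources: int = 5
    corruption_prob: float = 0.1
    corruption_modes: dict = field(default_factory=lambda: {
        "stereo_flip": 0.6, "substituent_swap": 0.25,
        "connectivity_change": 0.15})
    salt_form_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.corruption_prob <= 1.0
                and 0.0 <= self.salt_form_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_compounds < 1 or self.n_reference_sources < 1 \
                or self.n_structural_sources < 1:
            raise ValueError("world needs >=1 compound and >=1 source of each role")
        unknown = set(self.corruption_modes) - set(CORRUPTION_MODES)
        if unknown:
            raise ValueError(f"unknown corruption modes: {sorted(unknown)}")
        total = sum(self.corruption_modes.values())
        if self.corruption_modes and abs(total - 1.0) > 1e-9:
            raise ValueError("corruption mode weights must sum to 1")


# ---------------------------------------------------------------------------
# corruption operators

def _flip_stereo(mol: Chem.Mol, rng: np.random.Generator) -> Chem.Mol:
    centers = [a.GetIdx() for a in mol.GetAtoms()
               if a.GetChiralTag() in (Chem.ChiralType.CHI_TETRAHEDRAL_CW,
                                       Chem.ChiralType.CHI_TETRAHEDRAL_CCW)]
    if not centers:
        raise CorruptionNotApplicableError("no defined stereocenter to flip")
    out = Chem.Mol(mol)
    atom = out.GetAtomWithIdx(int(rng.choice(centers)))
    flipped = (Chem.ChiralType.CHI_TETRAHEDRAL_CW
               if atom.GetChiralTag() == Chem.ChiralType.CHI_TETRAHEDRAL_CCW
               else Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
    atom.SetChiralTag(flipped)
    return out


def _swap_substituent(mol: Chem.Mol, rng: np.random.Generator) -> Chem.Mol:
    candidates: list[tuple[int, int]] = []
    for a in mol.GetAtoms():
        if a.GetDegree() == 1:
            bond_type = a.GetBonds()[0].GetBondType()
            if bond_type == Chem.BondType.SINGLE \
                    and a.GetAtomicNum() in _SWAP_TABLE:
                candidates.append((a.GetIdx(), _SWAP_TABLE[a.GetAtomicNum()]))
            elif bond_type == Chem.BondType.DOUBLE \
                    and a.GetAtomicNum() in _DOUBLE_SWAP_TABLE:
                candidates.append((a.GetIdx(), _DOUBLE_SWAP_TABLE[a.GetAtomicNum()]))
        if a.GetTotalNumHs() >= 1:
            candidates.append((a.GetIdx(), _METHYLATE))  # swap an H for CH3
    if not candidates:
        raise CorruptionNotApplicableError("no swappable terminal substituent")
    order = [candidates[int(k)] for k in rng.permutation(len(candidates))]
    for idx, new_z in order:
        out = Chem.RWMol(mol)
        if new_z == _METHYLATE:
            atom = out.GetAtomWithIdx(int(idx))
            atom.SetNumExplicitHs(atom.GetTotalNumHs() - 1)
            atom.SetNoImplicit(True)
            new_idx = out.AddAtom(Chem.Atom(6))
            out.AddBond(int(idx), new_idx, Chem.BondType.SINGLE)
        else:
            atom = out.GetAtomWithIdx(int(idx))
            atom.SetAtomicNum(new_z)
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(0)
            atom.SetFormalCharge(0)
        try:
            result = out.GetMol()
            Chem.SanitizeMol(result)
            return result
        except Exception:
            continue
    raise CorruptionNotApplicableError("all substituent swaps were valence-illegal")


def _change_connectivity(mol: Chem.Mol, rng: np.random.Generator) -> Chem.Mol:
    terminals = [a.GetIdx() for a in mol.GetAtoms()
                 if a.GetDegree() == 1
                 and a.GetBonds()[0].GetBondType() == Chem.BondType.SINGLE]
    if not terminals:
        raise CorruptionNotApplicableError("no acyclic terminal bond to move")
    for t in rng.permutation(terminals):
        t = int(t)
        old_neighbor = mol.GetAtomWithIdx(t).GetNeighbors()[0].GetIdx()
        targets = [a.GetIdx() for a in mol.GetAtoms()
                   if a.GetIdx() not in (t, old_neighbor)
                   and a.GetTotalNumHs() >= 1]
        for c in rng.permutation(targets) if targets else []:
            c = int(c)
            out = Chem.RWMol(mol)
            out.RemoveBond(t, old_neighbor)
            out.AddBond(t, c, Chem.BondType.SINGLE)
            try:
                result = out.GetMol()
                Chem.SanitizeMol(result)
                if len(Chem.GetMolFrags(result)) == 1:
                    return result
            except Exception:
                continue
    raise CorruptionNotApplicableError("no legal bond reattachment found")


_CORRUPTION_FN = {"stereo_flip": _flip_stereo,
                  "substituent_swap": _swap_substituent,
                  "connectivity_change": _change_connectivity}


def apply_corruption(structure, mode: str, rng: np.random.Generator,
                     max_tries: int = 20) -> Chem.Mol:
    """Apply one corruption mode; the result parses and differs from the input.

    Raises :class:`CorruptionNotApplicableError` when the mode has nothing to
    act on (e.g. a stereo flip on an achiral molecule).
    """
    mol = structure if isinstance(structure, Chem.Mol) \
        else Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError("corruption input did not parse")
    before = Chem.MolToSmiles(mol)
    fn = _CORRUPTION_FN[mode]
    for _ in range(max_tries):
        out = fn(mol, rng)
        if Chem.MolToSmiles(out) != before:
            return out
    raise CorruptionNotApplicableError(
        f"mode {mode!r} could not produce a distinct structure")


# ---------------------------------------------------------------------------
# world generation

@dataclass
class GeneratedWorld:
    """In-memory world: per-source records, roles, and the ground truth."""

    spec: WorldSpec
    source_records: dict[str, tuple[list[SourceRecord], bool, bool]]
    truth: dict[str, str]  # query name -> true standardized canonical SMILES
    corrupted: set[tuple[str, str]]  # (query name, reference source)

    def registry(self) -> SourceRegistry:
        reg = SourceRegistry()
        for name in sorted(self.source_records):
            records, is_ref, is_struct = self.source_records[name]
            reg.add(FixtureSource(name, records, is_ref, is_struct))
        return reg

    def names(self) -> list[str]:
        return sorted(self.truth)

    def write(self, path) -> Path:
        """Write the fixture-directory form plus a ground-truth table."""
        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        for src_name in sorted(self.source_records):
            records, is_ref, is_struct = self.source_records[src_name]
            sub = root / src_name
            sub.mkdir(exist_ok=True)
            lines = ["# generated fixture source",
                     "roles: " + " ".join(
                         (["reference"] if is_ref else [])
                         + (["structural"] if is_struct else []))]
            for rec in sorted(records, key=lambda r: r.record_id):
                lines.append("")
                lines.append(f"record: {rec.record_id}")
                lines.append(f"smiles: {rec.raw_structure}")
                for syn in rec.synonyms:
                    lines.append(f"synonym: {syn}")
                for src, rid in rec.xrefs:
                    lines.append(f"xref: {src} {rid}")
            (sub / "index.txt").write_text("\n".join(lines) + "\n")
        truth_lines = ["name\tcanonical_smiles"]
        truth_lines += [f"{n}\t{self.truth[n]}" for n in sorted(self.truth)]
        (root / "ground_truth.tsv").write_text("\n".join(truth_lines) + "\n")
        return root


def load_ground_truth(path) -> dict[str, str]:
    """Read the ground-truth table written next to a generated fixture world."""
    truth = {}
    lines = (Path(path) / "ground_truth.tsv").read_text().splitlines()
    for line in lines[1:]:
        name, smiles = line.split("\t")
        truth[name] = smiles
    return truth


def _library_has_stereo() -> bool:
    for _, smiles in load_compound_library():
        mol = Chem.MolFromSmiles(smiles)
        if any(a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED
               for a in mol.GetAtoms()):
            return True
    return False


def _sample_mode(spec: WorldSpec, rng: np.random.Generator) -> str:
    r = rng.random()
    acc = 0.0
    for mode in CORRUPTION_MODES:
        acc += spec.corruption_modes.get(mode, 0.0)
        if r < acc:
            return mode
    return CORRUPTION_MODES[0]


def _apply_any_mode(mol, spec: WorldSpec, rng: np.random.Generator):
    """Apply one corruption, falling back across modes when one is not
    applicable (e.g. a stereo flip requested on an achiral molecule)."""
    modes = [m for m in CORRUPTION_MODES if spec.corruption_modes.get(m, 0) > 0]
    while modes:
        weights = [spec.corruption_modes[m] for m in modes]
        r = rng.random() * sum(weights)
        acc = 0.0
        chosen = modes[-1]
        for m, wt in zip(modes, weights):
            acc += wt
            if r < acc:
                chosen = m
                break
        try:
            return apply_corruption(mol, chosen, rng)
        except CorruptionNotApplicableError:
            modes.remove(chosen)
    raise CorruptionNotApplicableError("no corruption mode applicable")


def _effective_corruption(truth_mol, truth_smiles: str, taken: set[str],
                          spec: WorldSpec, rng: np.random.Generator,
                          max_tries: int = 100) -> tuple[str, str]:
    """Sample a corruption whose standardized form is new for this compound.

    Returns (raw SMILES of the corrupted record, its standardized SMILES).
    """
    for attempt in range(max_tries):
        # escalate to chained corruption operations when single edits cannot
        # yield enough distinct wrong structures for a small, rigid molecule
        n_ops = 1 + attempt // 25
        out = truth_mol
        try:
            for _ in range(n_ops):
                out = _apply_any_mode(out, spec, rng)
        except CorruptionNotApplicableError:
            continue
        raw = Chem.MolToSmiles(out)
        try:
            std = standardize(raw).canonical_smiles
        except ChemConsensusError:
            continue
        if std != truth_smiles and std not in taken:
            return raw, std
    raise RuntimeError("could not generate an effective corruption; "
                       "check corruption_modes against the compound library")


def _clean_representation(truth_mol, truth_raw: str, std_smiles: str,
                          rng: np.random.Generator) -> str:
    """One of the equivalent conventions a clean source might store."""
    mode = int(rng.integers(3))
    if mode == 0:
        return Chem.MolToSmiles(truth_mol)
    if mode == 1:  # kekulized convention
        copy = Chem.Mol(truth_mol)
        Chem.Kekulize(copy, clearAromaticFlags=True)
        return Chem.MolToSmiles(copy, kekuleSmiles=True)
    return std_smiles  # pH-7 protonated convention


def build_world(spec: WorldSpec) -> GeneratedWorld:
    """Generate a world in memory (deterministic in ``spec.seed``)."""
    if spec.corruption_modes.get("stereo_flip", 0.0) > 0 and not _library_has_stereo():
        raise ValueError("stereo_flip weight > 0 but the compound library "
                         "has no defined stereocenters")
    rng = np.random.default_rng(spec.seed)
    library = load_compound_library()
    ref_names = [f"refdb{j + 1}" for j in range(spec.n_reference_sources)]
    struct_names = [f"structdb{j + 1}" for j in range(spec.n_structural_sources)]

    records: dict[str, list[SourceRecord]] = {n: [] for n in ref_names}
    for n in struct_names:
        records.setdefault(n, [])
    truth: dict[str, str] = {}
    corrupted: set[tuple[str, str]] = set()

    for i in range(spec.n_compounds):
        lib_name, lib_smiles = library[i % len(library)]
        query_name = f"{lib_name}-{i:05d}"
        truth_mol = Chem.MolFromSmiles(lib_smiles)
        std_smiles = standardize(lib_smiles).canonical_smiles
        truth[query_name] = std_smiles
        taken: set[str] = set()

        for j, ref_name in enumerate(ref_names):
            struct_name = struct_names[j % len(struct_names)]
            struct_id = f"c{i:05d}r{j + 1}"
            synonyms = [query_name]
            if rng.random() < spec.corruption_prob:
                raw, std = _effective_corruption(truth_mol, std_smiles, taken,
                                                 spec, rng)
                taken.add(std)
                corrupted.add((query_name, ref_name))
            else:
                raw = _clean_representation(truth_mol, lib_smiles, std_smiles, rng)
                if rng.random() < spec.salt_form_prob:
                    salt = SALT_PARTNERS[int(rng.integers(len(SALT_PARTNERS)))]
                    raw = f"{raw}.{salt}"
                    synonyms.append(f"{query_name} {SALT_SUFFIX[salt]}")
            if rng.random() < 0.3:
                synonyms.append(f"{lib_name.replace('_', ' ')} INN-{i:05d}")
            records[struct_name].append(SourceRecord(
                source_name=struct_name, record_id=struct_id,
                raw_structure=raw, synonyms=tuple(synonyms)))
            records[ref_name].append(SourceRecord(
                source_name=ref_name, record_id=f"c{i:05d}",
                raw_structure=raw, synonyms=(query_name,),
                xrefs=((struct_name, struct_id),)))

    source_records = {}
    for n in ref_names:
        source_records[n] = (records[n], True, False)
    for n in struct_names:
        # a name may double as both roles when the spec asks for overlap
        if n in source_records:  # pragma: no cover - distinct name prefixes
            continue
        source_records[n] = (records[n], False, True)
    return GeneratedWorld(spec, source_records, truth, corrupted)


def generate_fixture_world(spec: WorldSpec, path) -> tuple[Path, dict[str, str]]:
    """Generate a world and write it as a fixture directory.

    Returns the directory path and the ground-truth name -> SMILES table.
    Identical specs (same seed) produce byte-identical directories.
    """
    world = build_world(spec)
    root = world.write(path)
    return root, dict(world.truth)
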