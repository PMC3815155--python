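"""Drug-likeness profiling and group comparison.

Descriptors follow Lipinski's operational definitions so the counts are
auditable:

* HBD — number of O-H and N-H hydrogens;
* HBA — number of N and O atoms, excluding pyrrole-type aromatic nitrogens
  and amide nitrogens (both have their lone pair tied up);
* rotatable bonds — non-ring single bonds between two non-terminal heavy
  atoms, amide C-N excluded (RDKit's strict rotor definition, which also
  treats ester and amidine C-X bonds as non-rotatable);
* Rule-of-5 violations over MW <= 500, HBD <= 5, HBA <= 10.  Computed logP
  is deliberately not part of the profile (prediction tools are too
  inaccurate to gate on), so violation counts range 0-3 and "passes with at
  most one violation" is judged on the three computable rules.

Two compound sets are compared per property with a Pearson chi-squared test
on binned counts; sparse bins are pooled before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors
from scipy import stats

from .standardize import parse_structure

_HBD_SMARTS = Chem.MolFromSmarts("[#7,#8;!H0]")
_HBA_SMARTS = Chem.MolFromSmarts(
    "[$([#7;!$([nH]);!$([NX3][CX3]=[OX1])]),$([#8])]")

#: default equal-width binnings per property: (lo, hi, width); values beyond
#: ``hi`` land in the last (overflow) bin.
DEFAULT_BINS: dict[str, tuple[float, float, float]] = {
    "mw": (0.0, 700.0, 50.0),
    "rotatable_bonds": (0.0, 15.0, 1.0),
    "hbd": (0.0, 10.0, 1.0),
    "hba": (0.0, 15.0, 1.0),
}


@dataclass(frozen=True)
class PropertyRecord:
    canonical_smiles: str
    mw: float
    rotatable_bonds: int
    hbd: int
    hba: int
    ro5_violations: int
    passes_ro5_one_violation: bool


def ro5_component_flags(mw: float, hbd: int, hba: int) -> tuple[bool, bool, bool]:
    """(MW > 500, HBD > 5, HBA > 10) violation flags."""
    return (mw > 500.0, hbd > 5, hba > 10)


def compute_properties(structure) -> PropertyRecord:
    """Descriptor profile of one standardized, single-fragment structure."""
    mol = structure if isinstance(structure, Chem.Mol) else parse_structure(structure)
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValueError("compute_properties expects a single-fragment structure")
    mw = Descriptors.MolWt(mol)
    rot = rdMolDescriptors.CalcNumRotatableBonds(
        mol, rdMolDescriptors.NumRotatableBondsOptions.Strict)
    hbd = sum(mol.GetAtomWithIdx(i).GetTotalNumHs(includeNeighbors=True)
              for (i,) in mol.GetSubstructMatches(_HBD_SMARTS))
    hba = len(mol.GetSubstructMatches(_HBA_SMARTS))
    violations = sum(ro5_component_flags(mw, hbd, hba))
    return PropertyRecord(
        canonical_smiles=Chem.MolToSmiles(mol),
        mw=mw,
        rotatable_bonds=rot,
        hbd=hbd,
        hba=hba,
        ro5_violations=violations,
        passes_ro5_one_violation=violations <= 1,
    )


def profile_set(structures) -> list[PropertyRecord]:
    """Profile an iterable of SMILES/Mol structures."""
    return [compute_properties(s) for s in structures]


def read_structure_file(path) -> list[Chem.Mol]:
    """Read an SDF (``.sdf``) or SMILES-per-line (anything else) compound set."""
    path = Path(path)
    mols: list[Chem.Mol] = []
    if path.suffix.lower() == ".sdf":
        for mol in Chem.SDMolSupplier(str(path)):
            if mol is not None:
                mols.append(mol)
    else:
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            mol = Chem.MolFromSmiles(line.split()[0])
            if mol is not None:
                mols.append(mol)
    return mols


# ---------------------------------------------------------------------------
# chi-squared comparison

def bin_values(values, binning) -> np.ndarray:
    """Histogram counts under an (lo, hi, width) equal-width binning.

    The last bin is open-ended so extreme values are counted, not dropped.
    """
    lo, hi, width = binning
    edges = np.arange(lo, hi + width / 2, width)
    edges = np.append(edges, np.inf)
    counts, _ = np.histogram(np.asarray(values, dtype=float), bins=edges)
    return counts


def merge_sparse_bins(table: np.ndarray, min_expected: float = 5.0) -> np.ndarray:
    """Pool adjacent bins until every bin's combined expected count >= threshold.

    Expected counts are taken under homogeneity (row totals x column share).
    Bins are pooled left to right; a sparse trailing bin is folded into its
    left neighbour.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        return table
    row_tot = table.sum(axis=1, keepdims=True)
    merged_cols: list[np.ndarray] = []
    acc = np.zeros(table.shape[0])
    for j in range(table.shape[1]):
        acc = acc + table[:, j]
        expected_min = (row_tot[:, 0] * acc.sum() / n).min()
        if expected_min >= min_expected:
            merged_cols.append(acc)
            acc = np.zeros(table.shape[0])
    if acc.sum() > 0:
        if merged_cols:
            merged_cols[-1] = merged_cols[-1] + acc
        else:
            merged_cols.append(acc)
    return np.column_stack(merged_cols)


def chi_squared_from_table(table) -> tuple[float, int, float]:
    """Pearson chi-squared statistic, df and p-value of a contingency table.

    No continuity correction (the plain Pearson statistic, also for 2x2).
    Zero-sum rows/columns are dropped; a single surviving row or column means
    the distributions are identical by construction: statistic 0, p 1.
    """
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0, 0, 1.0
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    if df == 0:
        return 0.0, 0, 1.0
    return float(stat), int(df), float(p)


def compare_groups(set_a, set_b, property_name: str,
                   binning: tuple[float, float, float] | None = None) -> dict:
    """Chi-squared comparison of one property between two compound sets.

    ``set_a``/``set_b`` are sequences of :class:`PropertyRecord` (or plain
    numbers).  Returns the statistic, degrees of freedom, p-value and the
    pooled contingency table actually tested.  Symmetric in its two sets.
    """
    if binning is None:
        if property_name not in DEFAULT_BINS:
            raise KeyError(f"no default binning for property {property_name!r}")
        binning = DEFAULT_BINS[property_name]

    def extract(records):
        vals = [getattr(r, property_name) if isinstance(r, PropertyRecord) else r
                for r in records]
        if not vals:
            raise ValueError("compare_groups requires two non-empty sets")
        return vals

    counts_a = bin_values(extract(set_a), binning)
    counts_b = bin_values(extract(set_b), binning)
    table = merge_sparse_bins(np.vstack([counts_a, counts_b]))
    stat, df, p = chi_squared_from_table(table)
    return {
        "property": property_name,
        "statistic": stat,
        "df": df,
        "p_value": p,
        "table": table.tolist(),
        "n_a": int(counts_a.sum()),
        "n_b": int(counts_b.sum()),
    }
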