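"""Assemble curated database entries from consensus results.

One resolved name becomes one entry: the winning standardized structure, the
cross-reference IDs that standardize to it, and the synonyms collected from
those winning records sorted by how many records carry each name.  Entries
whose structures are identical — different salt forms or brand names of one
API — are merged into a single record, which is why the output database has
fewer rows than input names.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem

from .consensus import ConsensusResult, Status, resolve_name
from .sources import SourceRegistry, normalize_name
from .standardize import StandardizedStructure

IdPair = tuple[str, str]


@dataclass
class CuratedEntry:
    """Final database row for one API."""

    preferred_name: str
    structure: StandardizedStructure
    xref_ids: dict[str, list[str]]  # structural source -> sorted record ids
    synonyms: list[tuple[str, int]]  # (name, frequency), sorted
    status: Status
    input_names: list[str]

    @property
    def canonical_smiles(self) -> str:
        return self.structure.canonical_smiles


def _sort_synonyms(counts: Counter, display: dict[str, str]) -> list[tuple[str, int]]:
    return [(display[k], n) for k, n in
            sorted(counts.items(), key=lambda kv: (-kv[1], display[kv[0]]))]


def collect_synonyms(winning_ids, sources: SourceRegistry) -> list[tuple[str, int]]:
    """Union of synonyms over the winning records, frequency-sorted.

    Frequency is the number of distinct records listing the name (after
    case/whitespace normalization); ties are broken lexicographically.  The
    first-seen spelling of each normalized name is kept for display.
    """
    counts: Counter = Counter()
    display: dict[str, str] = {}
    for source_name, record_id in winning_ids:
        record = sources.fetch_structure(source_name, record_id)
        seen_here: set[str] = set()
        for syn in record.synonyms:
            key = normalize_name(syn)
            if not key or key in seen_here:
                continue
            seen_here.add(key)
            counts[key] += 1
            display.setdefault(key, syn)
    return _sort_synonyms(counts, display)


def build_entry(result: ConsensusResult, sources: SourceRegistry) -> CuratedEntry:
    """Turn a consensus/majority result into a curated entry."""
    if result.winner is None:
        raise ValueError(f"cannot build an entry for status {result.status}")
    synonyms = collect_synonyms(result.winning_ids, sources)
    xref_ids: dict[str, list[str]] = {}
    for source_name, record_id in result.winning_ids:
        xref_ids.setdefault(source_name, []).append(record_id)
    for ids in xref_ids.values():
        ids.sort()
    preferred = synonyms[0][0] if synonyms else result.name
    return CuratedEntry(
        preferred_name=preferred,
        structure=result.winner,
        xref_ids=xref_ids,
        synonyms=synonyms,
        status=result.status,
        input_names=[result.name],
    )


def merge_duplicates(entries: list[CuratedEntry]) -> list[CuratedEntry]:
    """Merge entries sharing a canonical SMILES into one record each.

    Cross-references, input names and synonym counts are unioned; the merged
    preferred name is the top of the re-sorted synonym list, falling back to
    the lexicographically first input name.  Output is ordered by canonical
    SMILES so repeated runs diff cleanly.  Idempotent.
    """
    groups: dict[str, list[CuratedEntry]] = {}
    for entry in entries:
        groups.setdefault(entry.canonical_smiles, []).append(entry)

    merged: list[CuratedEntry] = []
    for smiles in sorted(groups):
        members = groups[smiles]
        counts: Counter = Counter()
        display: dict[str, str] = {}
        xref_ids: dict[str, set[str]] = {}
        input_names: list[str] = []
        provenance: set[IdPair] = set()
        # a merged record keeps the strongest outcome class among its members
        status = (Status.CONSENSUS
                  if all(m.status is Status.CONSENSUS for m in members)
                  else Status.MAJORITY)
        for m in members:
            for name, n in m.synonyms:
                key = normalize_name(name)
                counts[key] += n
                display.setdefault(key, name)
            for src, ids in m.xref_ids.items():
                xref_ids.setdefault(src, set()).update(ids)
            for name in m.input_names:
                if name not in input_names:
                    input_names.append(name)
            provenance.update(m.structure.provenance)
        synonyms = _sort_synonyms(counts, display)
        preferred = synonyms[0][0] if synonyms else sorted(input_names)[0]
        merged.append(CuratedEntry(
            preferred_name=preferred,
            structure=members[0].structure.with_provenance(sorted(provenance)),
            xref_ids={src: sorted(ids) for src, ids in sorted(xref_ids.items())},
            synonyms=synonyms,
            status=status,
            input_names=input_names,
        ))
    return merged


@dataclass
class RunSummary:
    """Outcome breakdown of a pipeline run (count and share per class)."""

    n_names: int = 0
    counts: dict[str, int] = field(default_factory=dict)
    no_majority_names: list[str] = field(default_factory=list)
    not_found_names: list[str] = field(default_factory=list)
    nonresponsive_sources: list[str] = field(default_factory=list)
    n_entries: int = 0

    @property
    def fractions(self) -> dict[str, float]:
        if self.n_names == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / self.n_names for k, v in self.counts.items()}

    def to_dict(self) -> dict:
        return {
            "n_names": self.n_names,
            "n_entries": self.n_entries,
            "counts": dict(self.counts),
            "percentages": {k: round(100.0 * v, 2)
                            for k, v in self.fractions.items()},
            "no_majority_names": list(self.no_majority_names),
            "not_found_names": list(self.not_found_names),
            "nonresponsive_sources": sorted(set(self.nonresponsive_sources)),
        }


def run_pipeline(names, sources: SourceRegistry,
                 ) -> tuple[list[CuratedEntry], RunSummary,
                            dict[str, ConsensusResult]]:
    """Resolve every name, assemble + merge entries, summarize outcomes.

    Returns the merged entry list (ordered by canonical SMILES), the run
    summary, and the per-name results for reporting.  Names resolving to
    ``no_majority`` or ``not_found`` produce no entry and are listed in the
    summary instead, so every input name is accounted for exactly once.
    """
    summary = RunSummary(counts={s.value: 0 for s in Status})
    results: dict[str, ConsensusResult] = {}
    entries: list[CuratedEntry] = []
    for name in names:
        result = resolve_name(name, sources)
        results[name] = result
        summary.n_names += 1
        summary.counts[result.status.value] += 1
        summary.nonresponsive_sources.extend(result.nonresponsive_sources)
        if result.status in (Status.CONSENSUS, Status.MAJORITY):
            entries.append(build_entry(result, sources))
        elif result.status is Status.NO_MAJORITY:
            summary.no_majority_names.append(name)
        else:
            summary.not_found_names.append(name)
    merged = merge_duplicates(entries)
    summary.n_entries = len(merged)
    return merged, summary, results


# ---------------------------------------------------------------------------
# writers

def write_entries_sdf(entries, path) -> None:
    """Write the curated database as an SDF file with annotation fields."""
    writer = Chem.SDWriter(str(path))
    try:
        for entry in entries:
            mol = Chem.MolFromSmiles(entry.canonical_smiles)
            if mol is None:  # pragma: no cover - entries hold valid SMILES
                continue
            mol.SetProp("_Name", entry.preferred_name)
            mol.SetProp("preferred_name", entry.preferred_name)
            mol.SetProp("status", entry.status.value)
            mol.SetProp("canonical_smiles", entry.canonical_smiles)
            mol.SetProp("xref_ids", json.dumps(entry.xref_ids))
            mol.SetProp("synonyms", "; ".join(
                f"{name} ({n})" for name, n in entry.synonyms))
            mol.SetProp("input_names", "; ".join(entry.input_names))
            writer.write(mol)
    finally:
        writer.close()


def write_entries_table(entries, path) -> None:
    """Write one tab-separated row per entry."""
    import pandas as pd

    rows = [{
        "canonical_smiles": e.canonical_smiles,
        "preferred_name": e.preferred_name,
        "status": e.status.value,
        "formula": e.structure.parent_formula,
        "xref_ids": json.dumps(e.xref_ids),
        "synonyms": json.dumps(e.synonyms),
        "input_names": json.dumps(e.input_names),
    } for e in entries]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary_json(summary: RunSummary, path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
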