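"""Chemical-record sources: the contract and a deterministic local backend.

A *reference* source is queried by compound name and answers with structural
database IDs (its own and cross-referenced foreign IDs).  A *structural*
source is queried by record ID and answers with the stored structure record.
Real-world databases (PubChem-, ChemSpider-, DrugBank-like services) usually
play both roles; the contract here keeps the roles explicit so the voting
layer can poll every reference source and fetch from every structural source.

The shipped backend is a plain-text fixture directory so the entire pipeline
runs deterministically offline::

    world/
      <source_name>/
        index.txt        # records: structure, synonyms, cross-references
        <id>.mol         # optional SDF V2000 blocks referenced by index.txt

``index.txt`` grammar (line oriented, ``#`` comments)::

    roles: reference structural

    record: 107882
    name: Apomorphine hydrochloride
    smiles: ...            # or  molfile: 107882.mol
    synonym: apomorphine
    xref: chemspider 10302

Name matching is case-insensitive, collapses whitespace runs and strips
surrounding punctuation; there is deliberately no fuzzy matching, since an
edit-distance match would silently change vote counts.
"""

from __future__ import annotations

import abc
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

from .errors import (
    FixtureFormatError,
    RecordNotFoundError,
    SourceError,
    StructureParseError,
    UnknownSourceError,
)
from .standardize import parse_structure

_WS_RUN = re.compile(r"\s+")
_STRIP_CHARS = string.punctuation + string.whitespace


def normalize_name(name: str) -> str:
    """Normalization applied to every name before comparison.

    Lower-case, collapse internal whitespace runs to one space, strip
    leading/trailing punctuation and whitespace.
    """
    return _WS_RUN.sub(" ", name.strip(_STRIP_CHARS)).casefold()


@dataclass(frozen=True)
class SourceRecord:
    """One record in one source."""

    source_name: str
    record_id: str
    raw_structure: str  # molfile block or SMILES string
    synonyms: tuple[str, ...] = ()
    xrefs: tuple[tuple[str, str], ...] = ()  # (foreign source, foreign id)

    @property
    def coordinates(self) -> tuple[str, str]:
        return (self.source_name, self.record_id)


@dataclass(frozen=True)
class ReferenceHit:
    """Answer of one reference source to one name query."""

    reference_source: str
    returned_ids: tuple[tuple[str, str], ...]  # ordered, duplicate-free

    def __post_init__(self):
        if len(set(self.returned_ids)) != len(self.returned_ids):
            raise ValueError("duplicate (source, id) pair within one hit")

    @property
    def n_ids(self) -> int:
        return len(self.returned_ids)


class ChemicalSource(abc.ABC):
    """Contract every backend (fixture or live adapter) implements."""

    name: str
    is_reference: bool = True
    is_structural: bool = True

    @abc.abstractmethod
    def lookup(self, name: str) -> ReferenceHit:
        """Name -> structural IDs (empty hit when the name is unknown)."""

    @abc.abstractmethod
    def fetch(self, record_id: str) -> SourceRecord:
        """Record ID -> full record; RecordNotFoundError when absent."""


class FixtureSource(ChemicalSource):
    """In-memory source backed by a record list (what ``index.txt`` parses to)."""

    def __init__(self, name: str, records: Iterable[SourceRecord],
                 is_reference: bool = True, is_structural: bool = True):
        self.name = name
        self.is_reference = is_reference
        self.is_structural = is_structural
        self._records: dict[str, SourceRecord] = {}
        self._by_name: dict[str, list[str]] = {}
        for rec in records:
            if rec.record_id in self._records:
                raise ValueError(
                    f"duplicate record id {rec.record_id!r} in source {name!r}")
            self._records[rec.record_id] = rec
            for syn in rec.synonyms:
                self._by_name.setdefault(normalize_name(syn), []).append(
                    rec.record_id)

    def __len__(self) -> int:
        return len(self._records)

    def record_ids(self) -> list[str]:
        return sorted(self._records)

    def records(self) -> Iterator[SourceRecord]:
        for rid in self.record_ids():
            yield self._records[rid]

    def lookup(self, name: str) -> ReferenceHit:
        ids: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for rid in self._by_name.get(normalize_name(name), ()):
            rec = self._records[rid]
            candidates = []
            if self.is_structural:
                candidates.append((self.name, rid))
            candidates.extend(rec.xrefs)
            for pair in candidates:
                if pair not in seen:
                    seen.add(pair)
                    ids.append(pair)
        return ReferenceHit(self.name, tuple(ids))

    def fetch(self, record_id: str) -> SourceRecord:
        try:
            rec = self._records[record_id]
        except KeyError:
            raise RecordNotFoundError(self.name, record_id) from None
        try:
            parse_structure(rec.raw_structure)
        except StructureParseError:
            raise StructureParseError("stored structure failed to parse",
                                      self.name, record_id) from None
        return rec


class CallableSource(ChemicalSource):
    """Adapter contract for live web services (PubChem-PUG / ChemSpider-like).

    The two callables perform the actual transport (HTTP, caching, retry);
    they must raise :class:`SourceError` on transport failure.  Disabled by
    default everywhere: nothing in the package instantiates one, and the test
    suite never exercises network access.
    """

    def __init__(self, name: str,
                 lookup_fn: Callable[[str], ReferenceHit],
                 fetch_fn: Callable[[str], SourceRecord],
                 is_reference: bool = True, is_structural: bool = True):
        self.name = name
        self._lookup_fn = lookup_fn
        self._fetch_fn = fetch_fn
        self.is_reference = is_reference
        self.is_structural = is_structural

    def lookup(self, name: str) -> ReferenceHit:
        try:
            return self._lookup_fn(name)
        except SourceError:
            raise
        except Exception as exc:
            raise SourceError(self.name, str(exc))

    def fetch(self, record_id: str) -> SourceRecord:
        try:
            return self._fetch_fn(record_id)
        except (SourceError, RecordNotFoundError):
            raise
        except Exception as exc:
            raise SourceError(self.name, str(exc))


@dataclass
class SourceRegistry:
    """The set of sources one curation run polls."""

    sources: dict[str, ChemicalSource] = field(default_factory=dict)

    def add(self, source: ChemicalSource) -> None:
        if source.name in self.sources:
            raise ValueError(f"source {source.name!r} already registered")
        self.sources[source.name] = source

    def __contains__(self, name: str) -> bool:
        return name in self.sources

    def __getitem__(self, name: str) -> ChemicalSource:
        try:
            return self.sources[name]
        except KeyError:
            raise UnknownSourceError(name) from None

    def reference_sources(self) -> list[ChemicalSource]:
        return [s for n, s in sorted(self.sources.items()) if s.is_reference]

    def structural_sources(self) -> list[ChemicalSource]:
        return [s for n, s in sorted(self.sources.items()) if s.is_structural]

    def fetch_structure(self, source_name: str, record_id: str) -> SourceRecord:
        return self[source_name].fetch(record_id)


def lookup_by_name(name: str, source: ChemicalSource) -> ReferenceHit:
    """Query one reference source by compound name.

    Raises ValueError on an empty name and :class:`SourceError` when the
    source itself fails; an unknown name yields an *empty* hit, which is a
    normal answer, not an error.
    """
    if not name or not name.strip():
        raise ValueError("empty name")
    return source.lookup(name)


def fetch_structure(source_name: str, record_id: str,
                    sources: SourceRegistry) -> SourceRecord:
    """Fetch one full record from the named structural source."""
    return sources.fetch_structure(source_name, record_id)


# ---------------------------------------------------------------------------
# fixture directory loading

def _parse_index(path: Path, source_name: str) -> tuple[list[SourceRecord], bool, bool]:
    records: list[SourceRecord] = []
    is_reference = True
    is_structural = True
    current: dict | None = None

    def close(line_no: int):
        nonlocal current
        if current is None:
            return
        if current["structure"] is None:
            raise FixtureFormatError(path, line_no,
                                     f"record {current['id']!r} has no structure")
        records.append(SourceRecord(
            source_name=source_name,
            record_id=current["id"],
            raw_structure=current["structure"],
            synonyms=tuple(current["synonyms"]),
            xrefs=tuple(current["xrefs"]),
        ))
        current = None

    line_no = 0
    for line_no, raw_line in enumerate(path.read_text().splitlines(), start=1):
        line = raw_line.split("#", 1)[0].strip() if not raw_line.lstrip().startswith("#") \
            else ""
        if not line:
            continue
        if ":" not in line:
            raise FixtureFormatError(path, line_no, f"expected 'key: value', got {line!r}")
        key, _, value = line.partition(":")
        key = key.strip().casefold()
        value = value.strip()
        if key == "roles":
            roles = set(value.split())
            bad = roles - {"reference", "structural"}
            if bad or not roles:
                raise FixtureFormatError(path, line_no, f"bad roles {value!r}")
            is_reference = "reference" in roles
            is_structural = "structural" in roles
        elif key == "record":
            close(line_no)
            if not value:
                raise FixtureFormatError(path, line_no, "record id missing")
            current = {"id": value, "structure": None, "synonyms": [], "xrefs": []}
        elif current is None:
            raise FixtureFormatError(path, line_no, f"{key!r} outside a record block")
        elif key == "smiles":
            current["structure"] = value
        elif key == "molfile":
            mol_path = path.parent / value
            if not mol_path.is_file():
                raise FixtureFormatError(path, line_no,
                                         f"referenced molfile {value!r} missing")
            current["structure"] = mol_path.read_text()
        elif key in ("name", "synonym"):
            current["synonyms"].append(value)
        elif key == "xref":
            parts = value.split()
            if len(parts) != 2:
                raise FixtureFormatError(path, line_no,
                                         f"xref needs '<source> <id>', got {value!r}")
            current["xrefs"].append((parts[0], parts[1]))
        else:
            raise FixtureFormatError(path, line_no, f"unknown key {key!r}")
    close(line_no)
    return records, is_reference, is_structural


def load_fixture_world(path) -> SourceRegistry:
    """Load a fixture directory (one subdirectory per source) into a registry.

    Loading is order-independent; two loads of the same directory answer all
    queries identically.  Non-directory entries (e.g. a ground-truth table)
    are ignored.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"fixture world directory not found: {root}")
    registry = SourceRegistry()
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        index = sub / "index.txt"
        if not index.is_file():
            raise FixtureFormatError(index, 0, "missing index.txt")
        records, is_ref, is_struct = _parse_index(index, sub.name)
        try:
            registry.add(FixtureSource(sub.name, records, is_ref, is_struct))
        except ValueError as exc:
            raise FixtureFormatError(index, 0, str(exc)) from None
    return registry
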