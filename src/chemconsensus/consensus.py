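"""Fractional rank-by-vote consensus over conflicting chemical records.

Given a compound name, every reference source is polled and answers with a
list of structural-database IDs.  A source returning k IDs distributes one
unit of vote mass as 1/k per ID, so every responsive source carries equal
weight no matter how many cross-references it emits.  IDs are then resolved
to structures, structures are standardized, and the votes of all IDs that
collapse onto the same canonical isomeric SMILES are added.  The outcome is

* ``consensus``   — every candidate standardizes to one structure;
* ``majority``    — one structure's vote strictly exceeds every other;
* ``no_majority`` — a tie at the top (or nothing standardizable): the name
  is flagged for manual review, never guessed;
* ``not_found``   — no source returned any ID for the name.

Votes are kept as exact :class:`fractions.Fraction` values throughout: with
denominators like 3 and 7 in play, float arithmetic cannot distinguish a
genuine tie from rounding noise, and ties change the outcome class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .errors import (
    ChemConsensusError,
    DuplicateSourceError,
    SourceError,
)
from .sources import ReferenceHit, SourceRegistry, lookup_by_name
from .standardize import StandardizedStructure, standardize

IdPair = tuple[str, str]


class Status(str, enum.Enum):
    CONSENSUS = "consensus"
    MAJORITY = "majority"
    NO_MAJORITY = "no_majority"
    NOT_FOUND = "not_found"


@dataclass
class VoteTally:
    """Fractional votes per structural ID and, once standardized, per structure."""

    id_votes: dict[IdPair, Fraction] = field(default_factory=dict)
    structure_votes: dict[str, Fraction] = field(default_factory=dict)
    contributing_sources: set[str] = field(default_factory=set)
    forfeited_ids: dict[IdPair, Fraction] = field(default_factory=dict)

    @property
    def total_id_mass(self) -> Fraction:
        return sum(self.id_votes.values(), Fraction(0))

    @property
    def forfeited_mass(self) -> Fraction:
        return sum(self.forfeited_ids.values(), Fraction(0))


@dataclass
class ConsensusResult:
    """Outcome of resolving one name."""

    name: str
    status: Status
    winner: StandardizedStructure | None
    tally: VoteTally
    winning_ids: tuple[IdPair, ...] = ()
    structures: dict[IdPair, StandardizedStructure] = field(default_factory=dict)
    nonresponsive_sources: tuple[str, ...] = ()
    failures: dict[IdPair, str] = field(default_factory=dict)

    def report(self) -> dict:
        """JSON-serializable per-name report with exact and decimal votes."""
        ranked = rank_ids(self.tally)
        return {
            "name": self.name,
            "status": self.status.value,
            "winner_smiles": self.winner.canonical_smiles if self.winner else None,
            "winning_ids": [list(p) for p in self.winning_ids],
            "ranked_ids": [
                {"source": s, "id": i,
                 "vote": str(self.tally.id_votes[(s, i)]),
                 "vote_decimal": float(self.tally.id_votes[(s, i)])}
                for s, i in ranked
            ],
            "structure_votes": {
                smi: {"vote": str(v), "vote_decimal": float(v)}
                for smi, v in sorted(self.tally.structure_votes.items())
            },
            "forfeited_ids": [
                {"source": s, "id": i, "vote": str(v), "reason": self.failures.get((s, i), "")}
                for (s, i), v in sorted(self.tally.forfeited_ids.items())
            ],
            "nonresponsive_sources": sorted(self.nonresponsive_sources),
        }


def tally_id_votes(hits: Iterable[ReferenceHit]) -> VoteTally:
    """Accumulate fractional votes: 1/k per ID from a source returning k IDs.

    Every source that returned at least one ID contributes total mass exactly
    one; empty hits contribute nothing.  Two hits from the same reference
    source are rejected — that would double-weight the source.
    """
    tally = VoteTally()
    seen_sources: set[str] = set()
    for hit in hits:
        if hit.reference_source in seen_sources:
            raise DuplicateSourceError(
                f"two hits from reference source {hit.reference_source!r}")
        seen_sources.add(hit.reference_source)
        if hit.n_ids == 0:
            continue
        share = Fraction(1, hit.n_ids)
        tally.contributing_sources.add(hit.reference_source)
        for pair in hit.returned_ids:
            tally.id_votes[pair] = tally.id_votes.get(pair, Fraction(0)) + share
    return tally


def rank_ids(tally: VoteTally) -> list[IdPair]:
    """IDs by descending vote; ties broken lexicographically by (source, id)."""
    return sorted(tally.id_votes, key=lambda p: (-tally.id_votes[p], p))


def build_consensus(
    tally: VoteTally,
    standardized: Mapping[IdPair, StandardizedStructure],
    name: str = "",
    nonresponsive: Sequence[str] = (),
    failures: Mapping[IdPair, str] | None = None,
) -> ConsensusResult:
    """Push ID votes onto standardized structures and classify the outcome.

    IDs missing from ``standardized`` forfeit their votes (fetch or
    standardization failure); the forfeited mass stays in the report so
    source decay is visible.  A tie at the top — including the degenerate
    case where every ID forfeited — is never broken silently: the name is
    flagged ``no_majority`` for manual review.
    """
    failures = dict(failures or {})
    tally.structure_votes = {}
    tally.forfeited_ids = {}
    for pair, vote in tally.id_votes.items():
        if pair in standardized:
            smi = standardized[pair].canonical_smiles
            tally.structure_votes[smi] = tally.structure_votes.get(
                smi, Fraction(0)) + vote
        else:
            tally.forfeited_ids[pair] = vote
            failures.setdefault(pair, "structure unavailable")

    if not tally.contributing_sources:
        return ConsensusResult(name, Status.NOT_FOUND, None, tally,
                               nonresponsive_sources=tuple(nonresponsive),
                               failures=failures)

    if not tally.structure_votes:
        return ConsensusResult(name, Status.NO_MAJORITY, None, tally,
                               structures=dict(standardized),
                               nonresponsive_sources=tuple(nonresponsive),
                               failures=failures)

    distinct = sorted(tally.structure_votes)
    top_smiles = max(distinct, key=lambda s: (tally.structure_votes[s], s))
    top_vote = tally.structure_votes[top_smiles]
    winners = [s for s in distinct if tally.structure_votes[s] == top_vote]

    if len(distinct) == 1:
        status = Status.CONSENSUS
    elif len(winners) == 1:
        status = Status.MAJORITY
    else:
        status = Status.NO_MAJORITY

    if status is Status.NO_MAJORITY:
        return ConsensusResult(name, status, None, tally,
                               structures=dict(standardized),
                               nonresponsive_sources=tuple(nonresponsive),
                               failures=failures)

    winner_smiles = winners[0]
    winning_ids = tuple(sorted(
        p for p, s in standardized.items()
        if s.canonical_smiles == winner_smiles and p in tally.id_votes))
    winner = standardized[winning_ids[0]].with_provenance(winning_ids)
    return ConsensusResult(name, status, winner, tally, winning_ids,
                           structures=dict(standardized),
                           nonresponsive_sources=tuple(nonresponsive),
                           failures=failures)


def resolve_name(name: str, sources: SourceRegistry) -> ConsensusResult:
    """End-to-end resolution of one compound name against a source registry.

    Polls every reference source (a failing source is recorded as
    non-responsive and skipped), tallies fractional votes, fetches and
    standardizes every voted structure, and classifies the outcome.
    """
    hits: list[ReferenceHit] = []
    nonresponsive: list[str] = []
    for source in sources.reference_sources():
        try:
            hits.append(lookup_by_name(name, source))
        except SourceError:
            nonresponsive.append(source.name)

    tally = tally_id_votes(hits)

    standardized: dict[IdPair, StandardizedStructure] = {}
    failures: dict[IdPair, str] = {}
    for pair in rank_ids(tally):
        src_name, record_id = pair
        try:
            record = sources.fetch_structure(src_name, record_id)
            standardized[pair] = standardize(record.raw_structure,
                                             provenance=[pair])
        except ChemConsensusError as exc:
            failures[pair] = f"{type(exc).__name__}: {exc}"

    return build_consensus(tally, standardized, name=name,
                           nonresponsive=nonresponsive, failures=failures)
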