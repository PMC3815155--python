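"""Fractional vote tallying, ranking and outcome classification."""

import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemconsensus import (
    FixtureSource,
    ReferenceHit,
    SourceRecord,
    SourceRegistry,
    Status,
    StandardizedStructure,
    build_consensus,
    rank_ids,
    resolve_name,
    tally_id_votes,
)
from chemconsensus.errors import DuplicateSourceError

from .oracles import brute_force_id_votes, brute_force_outcome


def struct(key: str) -> StandardizedStructure:
    """Minimal standardized-structure stand-in keyed by its SMILES string."""
    return StandardizedStructure(key, "", 0, 0)


class TestTally:
    def test_single_and_quarter_votes_add_to_five_fourths(self):
        hits = [
            ReferenceHit("pubchem", (("pubchem", "107882"),)),
            ReferenceHit("chemspider", (("chemspider", "10302"),
                                        ("pubchem", "107882"),
                                        ("chemspider", "96602"),
                                        ("chemspider", "157862"))),
        ]
        tally = tally_id_votes(hits)
        assert tally.id_votes[("pubchem", "107882")] == Fraction(5, 4)
        assert tally.id_votes[("chemspider", "10302")] == Fraction(1, 4)
        assert rank_ids(tally)[0] == ("pubchem", "107882")

    def test_single_source_single_id(self):
        tally = tally_id_votes([ReferenceHit("a", (("s", "1"),))])
        assert tally.id_votes == {("s", "1"): Fraction(1)}
        assert tally.total_id_mass == 1

    def test_empty_hits_contribute_nothing(self):
        tally = tally_id_votes([ReferenceHit("a", ())])
        assert tally.id_votes == {}
        assert tally.contributing_sources == set()

    def test_duplicate_reference_source_rejected(self):
        hits = [ReferenceHit("a", (("s", "1"),)), ReferenceHit("a", (("s", "2"),))]
        with pytest.raises(DuplicateSourceError):
            tally_id_votes(hits)

    def test_matches_brute_force_accumulation_on_random_hits(self):
        rng = random.Random(99)
        for _ in range(100):
            hit_list = []
            for s in range(rng.randint(1, 5)):
                ids = [("db%d" % rng.randint(0, 2), str(rng.randint(0, 9)))
                       for _ in range(rng.randint(0, 5))]
                deduped = list(dict.fromkeys(ids))
                hit_list.append((f"ref{s}", deduped))
            tally = tally_id_votes(
                [ReferenceHit(s, tuple(ids)) for s, ids in hit_list])
            assert tally.id_votes == brute_force_id_votes(hit_list)
            # per-source mass is exactly one for every contributing source
            assert tally.total_id_mass == len(
                [1 for _, ids in hit_list if ids])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(
        st.lists(st.tuples(st.sampled_from("abc"), st.text("0123456789",
                                                           min_size=1, max_size=2)),
                 max_size=6, unique=True),
        min_size=0, max_size=6))
    def test_vote_mass_conservation_property(self, id_lists):
        hits = [ReferenceHit(f"ref{i}", tuple(ids))
                for i, ids in enumerate(id_lists)]
        tally = tally_id_votes(hits)
        assert tally.total_id_mass == len(tally.contributing_sources)


class TestRanking:
    def test_empty_tally_ranks_empty(self):
        assert rank_ids(tally_id_votes([])) == []

    def test_ties_break_lexicographically_and_deterministically(self):
        hits = [ReferenceHit("a", (("z", "9"), ("b", "2"), ("b", "10")))]
        tally = tally_id_votes(hits)
        assert rank_ids(tally) == [("b", "10"), ("b", "2"), ("z", "9")]
        assert rank_ids(tally) == rank_ids(tally)


class TestBuildConsensus:
    def test_unanimous_structures_is_consensus(self):
        hits = [ReferenceHit("r1", (("s", "1"),)),
                ReferenceHit("r2", (("s", "1"), ("s", "2")))]
        tally = tally_id_votes(hits)
        result = build_consensus(tally, {("s", "1"): struct("X"),
                                         ("s", "2"): struct("X")})
        assert result.status is Status.CONSENSUS
        assert result.winner.canonical_smiles == "X"
        assert set(result.winning_ids) == {("s", "1"), ("s", "2")}

    def test_strict_majority_wins(self):
        hits = [ReferenceHit(f"r{i}", ((f"s{i}", "1"),)) for i in range(4)]
        standardized = {("s0", "1"): struct("A"), ("s1", "1"): struct("A"),
                        ("s2", "1"): struct("A"), ("s3", "1"): struct("B")}
        result = build_consensus(tally_id_votes(hits), standardized)
        assert result.status is Status.MAJORITY
        assert result.winner.canonical_smiles == "A"
        assert result.tally.structure_votes["A"] == Fraction(3)

    def test_exact_tie_is_flagged_not_guessed(self):
        hits = [ReferenceHit(f"r{i}", ((f"s{i}", "1"),)) for i in range(4)]
        standardized = {("s0", "1"): struct("A"), ("s1", "1"): struct("A"),
                        ("s2", "1"): struct("B"), ("s3", "1"): struct("B")}
        result = build_consensus(tally_id_votes(hits), standardized)
        assert result.status is Status.NO_MAJORITY
        assert result.winner is None

    def test_no_contributing_sources_is_not_found(self):
        result = build_consensus(tally_id_votes([ReferenceHit("r", ())]), {})
        assert result.status is Status.NOT_FOUND

    def test_forfeited_votes_are_conserved_and_reported(self):
        hits = [ReferenceHit("r1", (("s", "1"), ("s", "2"), ("s", "3")))]
        tally = tally_id_votes(hits)
        result = build_consensus(tally, {("s", "1"): struct("A")})
        assert result.tally.forfeited_mass == Fraction(2, 3)
        assert result.tally.forfeited_mass + sum(
            result.tally.structure_votes.values()) == tally.total_id_mass
        assert set(result.tally.forfeited_ids) == {("s", "2"), ("s", "3")}

    def test_all_forfeited_goes_to_manual_review(self):
        hits = [ReferenceHit("r1", (("s", "1"),))]
        result = build_consensus(tally_id_votes(hits), {})
        assert result.status is Status.NO_MAJORITY

    def test_matches_brute_force_on_random_small_worlds(self):
        rng = random.Random(7)
        structures = "ABCDEFGH"
        for _ in range(300):
            n_sources = rng.randint(1, 6)
            universe = [("db", str(i)) for i in range(10)]
            hit_list = []
            for s in range(n_sources):
                ids = rng.sample(universe, rng.randint(0, 4))
                hit_list.append((f"ref{s}", ids))
            structure_of = {
                pair: (rng.choice(structures) if rng.random() > 0.15 else None)
                for pair in universe}
            status, winner = brute_force_outcome(hit_list, structure_of)
            standardized = {p: struct(k) for p, k in structure_of.items()
                            if k is not None}
            result = build_consensus(
                tally_id_votes([ReferenceHit(s, tuple(i)) for s, i in hit_list]),
                standardized)
            assert result.status.value == status
            got_winner = result.winner.canonical_smiles if result.winner else None
            assert got_winner == winner

    def test_adding_a_clean_source_never_dethrones_the_winner(self):
        rng = random.Random(21)
        for _ in range(50):
            n = rng.randint(2, 5)
            hit_list = [(f"ref{i}", [(f"s{i}", "1")]) for i in range(n)]
            structure_of = {(f"s{i}", "1"): rng.choice("AB") for i in range(n)}
            standardized = {p: struct(k) for p, k in structure_of.items()}
            before = build_consensus(
                tally_id_votes([ReferenceHit(s, tuple(i)) for s, i in hit_list]),
                standardized)
            if before.winner is None:
                continue
            winner_key = before.winner.canonical_smiles
            hit_list.append(("ref_extra", [("s_extra", "1")]))
            standardized[("s_extra", "1")] = struct(winner_key)
            after = build_consensus(
                tally_id_votes([ReferenceHit(s, tuple(i)) for s, i in hit_list]),
                standardized)
            assert after.winner is not None
            assert after.winner.canonical_smiles == winner_key


class TestResolveName:
    def test_worked_example_resolves_to_consensus(self, example_registry):
        result = resolve_name("Apomorphine Hydrochloride", example_registry)
        assert result.status is Status.CONSENSUS
        assert result.tally.id_votes[("pubchem", "107882")] == Fraction(5, 4)
        assert result.winner is not None

    def test_unknown_name_not_found(self, example_registry):
        assert resolve_name("zzz-nonexistent", example_registry).status \
            is Status.NOT_FOUND

    def test_zero_noise_world_reaches_consensus_on_truth(self, clean_world):
        registry = clean_world.registry()
        for name in clean_world.names():
            result = resolve_name(name, registry)
            assert result.status is Status.CONSENSUS
            assert result.winner.canonical_smiles == clean_world.truth[name]

    def test_failing_source_is_recorded_not_fatal(self, example_registry):
        from chemconsensus.errors import SourceError
        from chemconsensus.sources import CallableSource

        def boom(_):
            raise SourceError("flaky")

        registry = SourceRegistry()
        for src in example_registry.sources.values():
            registry.add(src)
        registry.add(CallableSource("flaky", boom, boom, is_structural=False))
        result = resolve_name("Apomorphine Hydrochloride", registry)
        assert result.status is Status.CONSENSUS
        assert result.nonresponsive_sources == ("flaky",)

    def test_report_is_json_serializable(self, example_registry):
        import json
        result = resolve_name("Apomorphine Hydrochloride", example_registry)
        payload = json.loads(json.dumps(result.report()))
        assert payload["status"] == "consensus"
        assert payload["ranked_ids"][0]["vote"] == "5/4"
        assert payload["ranked_ids"][0]["vote_decimal"] == 1.25
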