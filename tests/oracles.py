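"""Independent brute-force reference implementations used only by tests.

Deliberately written as plain accumulation loops over explicit data, with no
imports from the package's consensus internals, so they stay an independent
check of the fractional-vote arithmetic and outcome classification.
"""

from fractions import Fraction


def brute_force_id_votes(hit_list):
    """hit_list: [(source_name, [(struct_source, id), ...]), ...]."""
    votes = {}
    for _source, ids in hit_list:
        if len(ids) == 0:
            continue
        for pair in ids:
            votes[pair] = votes.get(pair, Fraction(0)) + Fraction(1, len(ids))
    return votes


def brute_force_outcome(hit_list, structure_of):
    """Classify the outcome by direct enumeration.

    ``structure_of`` maps (source, id) -> structure key, or None for an ID
    whose structure is unavailable (its votes are forfeited).
    Returns (status string, winning structure key or None).
    """
    id_votes = brute_force_id_votes(hit_list)
    contributing = {s for s, ids in hit_list if len(ids) > 0}
    if not contributing:
        return "not_found", None
    struct_votes = {}
    for pair, v in id_votes.items():
        key = structure_of.get(pair)
        if key is None:
            continue
        struct_votes[key] = struct_votes.get(key, Fraction(0)) + v
    if not struct_votes:
        return "no_majority", None
    best = max(struct_votes.values())
    winners = [k for k, v in struct_votes.items() if v == best]
    if len(struct_votes) == 1:
        return "consensus", winners[0]
    if len(winners) == 1:
        return "majority", winners[0]
    return "no_majority", None


def brute_force_synonym_counts(records):
    """records: iterable of synonym lists; returns normalized-name -> count."""
    counts = {}
    for synonyms in records:
        seen = set()
        for name in synonyms:
            key = " ".join(name.split()).strip().casefold()
            if key and key not in seen:
                seen.add(key)
                counts[key] = counts.get(key, 0) + 1
    return counts


def brute_force_group_by_structure(entries):
    """entries: [(key, payload)]; returns {key: [payloads]}."""
    groups = {}
    for key, payload in entries:
        groups.setdefault(key, []).append(payload)
    return groups
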