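"""Bubble acceptance under the conflict rule, greedy linking, majority-vote
phasing, and linear haplotype emission."""

from __future__ import annotations

import pytest

from hapscaffold.bubbles import make_bubble
from hapscaffold.formats import ContigRecord
from hapscaffold.graph import ContigEnd, End, ScaffoldGraph, edge_key
from hapscaffold.phasing import (
    Chain,
    IncludedEdgeSet,
    MonoElement,
    PairElement,
    accept_bubbles,
    build_chains,
    emit_haplotypes,
    greedy_link,
    phase_chains,
    revcomp,
    round_half_away,
)


def ce(cid, end):
    return ContigEnd(cid, End(end))


def k(a, ea, b, eb):
    return edge_key(ce(a, ea), ce(b, eb))


def _bubble(c1, a, b, c2):
    return make_bubble(
        c1, a, b, c2,
        k(c1, "3p", a, "5p"), k(c1, "3p", b, "5p"),
        k(a, "3p", c2, "5p"), k(b, "3p", c2, "5p"),
    )


# ---------------------------------------------------------------------------
# acceptance


def test_competing_imperfect_bubbles_first_wins():
    # two candidates sharing heterotig a on the same end: occupancy lets
    # only the higher-ranked one in
    b1 = _bubble("c1", "a", "b", "c2")
    b2 = make_bubble(
        "c1", "a", "x", "c3",
        k("c1", "3p", "a", "5p"), k("c1", "3p", "x", "5p"),
        k("a", "3p", "c3", "5p"), k("x", "3p", "c3", "5p"),
    )
    inc = IncludedEdgeSet()
    accepted, rejected = accept_bubbles([], [b1, b2], inc)
    assert accepted == [b1] and rejected == [b2]


def test_bubble_reusing_included_edge_disallowed():
    perfect = _bubble("c1", "a", "b", "c2")
    reuse = make_bubble(
        "c2", "p", "q", "c3",
        perfect.e_ac2, k("c2", "5p", "q", "5p"),  # re-uses a-c2, touches c2 5'
        k("p", "3p", "c3", "5p"), k("q", "3p", "c3", "5p"),
    )
    inc = IncludedEdgeSet()
    accepted, rejected = accept_bubbles([perfect], [reuse], inc)
    assert rejected == [reuse]


def test_disjoint_positive_bubble_accepted():
    inc = IncludedEdgeSet()
    accepted, rejected = accept_bubbles(
        [_bubble("c1", "a", "b", "c2")], [_bubble("d1", "p", "q", "d2")], inc
    )
    assert len(accepted) == 2 and not rejected


def test_chain_of_bubbles_shares_flank_without_conflict():
    b1 = _bubble("c1", "a", "b", "c2")
    b2 = _bubble("c2", "d", "e", "c3")  # uses c2's 3' end; b1 used its 5'
    inc = IncludedEdgeSet()
    accepted, _ = accept_bubbles([b1, b2], [], inc)
    assert len(accepted) == 2
    inc.assert_occupancy()
    inc.assert_bubble_purity()


def test_cycle_closing_bubble_rejected():
    b1 = _bubble("c1", "a", "b", "c2")
    back = make_bubble(
        "c2", "p", "q", "c1",
        k("c2", "3p", "p", "5p"), k("c2", "3p", "q", "5p"),
        k("p", "3p", "c1", "5p"), k("q", "3p", "c1", "5p"),
    )
    inc = IncludedEdgeSet()
    accepted, rejected = accept_bubbles([b1], [back], inc)
    assert rejected == [back]


# ---------------------------------------------------------------------------
# greedy linking


def _graph_with(edges):
    lengths = {}
    g = ScaffoldGraph({})
    for (a, ea, b, eb, w) in edges:
        lengths[a] = lengths[b] = 500
        g.contig_lengths.update({a: 500, b: 500})
        for _ in range(w):
            g.add_gap_sample(ce(a, ea), ce(b, eb), 25)
    return g


def test_greedy_prefers_heavier_edge_per_end():
    g = _graph_with([("c", "3p", "x", "5p", 10), ("c", "3p", "y", "5p", 7)])
    inc = IncludedEdgeSet()
    added = greedy_link(g, inc)
    assert added == [k("c", "3p", "x", "5p")]


def test_equal_weight_tie_breaks_lexicographically():
    g = _graph_with([("c", "3p", "y", "5p", 8), ("c", "3p", "x", "5p", 8)])
    added = greedy_link(g, IncludedEdgeSet())
    assert added == [k("c", "3p", "x", "5p")]


def test_repeat_flagged_contig_skipped():
    g = _graph_with([("c", "3p", "r", "5p", 9), ("c", "3p", "x", "5p", 2)])
    g.repeat_flags = {"r"}
    added = greedy_link(g, IncludedEdgeSet())
    assert added == [k("c", "3p", "x", "5p")]


def test_greedy_never_closes_a_cycle():
    g = _graph_with(
        [
            ("a", "3p", "b", "5p", 9),
            ("b", "3p", "c", "5p", 8),
            ("c", "3p", "a", "5p", 7),  # would close the triangle
        ]
    )
    inc = IncludedEdgeSet()
    added = greedy_link(g, inc)
    assert len(added) == 2
    assert k("c", "3p", "a", "5p") not in inc.edges


# ---------------------------------------------------------------------------
# phasing


def _two_bubble_chain():
    b1 = _bubble("c1", "a1", "b1", "c2")
    b2 = _bubble("c2", "a2", "b2", "c3")
    chain = Chain(
        "scaffold1",
        [
            MonoElement("c1", "+"),
            PairElement(b1, "a1", "+", "b1", "+"),
            MonoElement("c2", "+"),
            PairElement(b2, "a2", "+", "b2", "+"),
            MonoElement("c3", "+"),
        ],
        [dict() for _ in range(4)],
    )
    return chain


def test_majority_vote_groups_linked_heterotigs():
    chain = _two_bubble_chain()
    links = {frozenset(("a1", "a2")): 5}
    groups, coloring, conflicts = phase_chains([chain], links)
    assert conflicts == 0
    members = {frozenset(g.members) for g in groups}
    assert members == {frozenset(("a1", "a2")), frozenset(("b1", "b2"))}
    assert coloring["a1"] == coloring["a2"] != coloring["b1"] == coloring["b2"]


def test_no_links_each_bubble_forms_own_group_pair():
    groups, _, _ = phase_chains([_two_bubble_chain()], {})
    assert len(groups) == 4
    assert sorted(len(g.members) for g in groups) == [1, 1, 1, 1]


def test_conflicting_votes_resolved_by_majority_and_counted():
    links = {frozenset(("a1", "a2")): 3, frozenset(("a1", "b2")): 1}
    groups, coloring, conflicts = phase_chains([_two_bubble_chain()], links)
    assert coloring["a1"] == coloring["a2"]
    assert conflicts == 1


def test_complementarity_invariant():
    chain = _two_bubble_chain()
    groups, _, _ = phase_chains([chain], {frozenset(("a1", "b2")): 2})
    by_id = {g.id: g for g in groups}
    all_hets = {"a1", "b1", "a2", "b2"}
    for g in groups:
        comp = by_id[g.complement_id]
        assert comp.complement_id == g.id
        assert not (set(g.members) & set(comp.members))
    # the two heterotigs of any bubble lie in complementary groups
    for b in (chain.pair_elements[0], chain.pair_elements[1]):
        ga = next(g for g in groups if b.a in g.members)
        assert b.b in by_id[ga.complement_id].members
    assert {m for g in groups for m in g.members} == all_hets


# ---------------------------------------------------------------------------
# emission


def _contig_set(**seqs):
    return {cid: ContigRecord(cid, seq) for cid, seq in seqs.items()}


def test_emitted_lengths_follow_gap_arithmetic():
    b = _bubble("c1", "a", "b", "c2")
    chain = Chain(
        "scaffold1",
        [MonoElement("c1", "+"), PairElement(b, "a", "+", "b", "+"), MonoElement("c2", "+")],
        [
            {frozenset(("c1", "a")): 50.0, frozenset(("c1", "b")): 50.0},
            {frozenset(("a", "c2")): 50.0, frozenset(("b", "c2")): 50.0},
        ],
    )
    contigs = _contig_set(c1="A" * 1000, a="C" * 300, b="G" * 300, c2="T" * 1000)
    hap1, hap2, _ = emit_haplotypes([chain], {"a": 1, "b": 2}, contigs)
    assert len(hap1[0][1]) == 1000 + 50 + 300 + 50 + 1000 == 2400
    assert len(hap2[0][1]) == 2400
    assert "C" in hap1[0][1] and "C" not in hap2[0][1]


def test_partial_bubble_leaves_length_matched_gap_on_other_haplotype():
    chain = Chain(
        "scaffold1",
        [MonoElement("c1", "+"), PairElement(None, "a", "+", None, "+")],
        [{frozenset(("c1", "a")): 20.0}],
    )
    contigs = _contig_set(c1="A" * 100, a="C" * 40)
    hap1, hap2, _ = emit_haplotypes([chain], {"a": 1}, contigs)
    assert len(hap1[0][1]) == 100 + 20 + 40
    assert hap2[0][1].endswith("N" * 40)  # heterotig-length placeholder


def test_negative_gap_floors_at_minimum_n_run():
    chain = Chain(
        "scaffold1",
        [MonoElement("c1", "+"), MonoElement("c2", "+")],
        [{frozenset(("c1", "c2")): -30.0}],
    )
    contigs = _contig_set(c1="A" * 100, c2="G" * 100)
    hap1, _, _ = emit_haplotypes([chain], {}, contigs, gap_floor=10)
    assert hap1[0][1] == "A" * 100 + "N" * 10 + "G" * 100


def test_reverse_orientation_emits_reverse_complement():
    chain = Chain(
        "scaffold1",
        [MonoElement("c1", "+"), MonoElement("c2", "-")],
        [{frozenset(("c1", "c2")): 5.0}],
    )
    contigs = _contig_set(c1="AACC", c2="AGGT")
    hap1, _, _ = emit_haplotypes([chain], {}, contigs, gap_floor=1)
    assert hap1[0][1] == "AACC" + "NNNNN" + revcomp("AGGT")


def test_singletons_emitted_identically_in_both_haplotypes():
    contigs = _contig_set(s1="ACGT")
    hap1, hap2, _ = emit_haplotypes([], {}, contigs, singletons=["s1"])
    assert hap1[0][1] == hap2[0][1] == "ACGT"
    assert hap1[0][0].endswith("_hap1") and hap2[0][0].endswith("_hap2")


def test_rounding_is_half_away_from_zero():
    assert round_half_away(10.5) == 11
    assert round_half_away(-10.5) == -11
    assert round_half_away(10.4) == 10


# ---------------------------------------------------------------------------
# chain building from an included set


def test_build_chains_recovers_order_and_orientation():
    b = _bubble("c1", "a", "b", "c2")
    inc = IncludedEdgeSet()
    accept_bubbles([b], [], inc)
    g = _graph_with(
        [
            ("c1", "3p", "a", "5p", 3), ("c1", "3p", "b", "5p", 3),
            ("a", "3p", "c2", "5p", 3), ("b", "3p", "c2", "5p", 3),
            ("c2", "3p", "d", "3p", 3),  # d attached by its 3' end -> reversed
        ]
    )
    greedy_link(g, inc)
    gaps = {e.key: e.gap_estimate for e in g.active_edges()}
    chains = build_chains(inc, gaps)
    assert len(chains) == 1
    els = chains[0].elements
    kinds = [type(e).__name__ for e in els]
    assert kinds == ["MonoElement", "PairElement", "MonoElement", "MonoElement"]
    assert els[0].contig == "c1" and els[0].orient == "+"
    assert els[3].contig == "d" and els[3].orient == "-"
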