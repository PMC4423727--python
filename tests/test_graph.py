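"""Scaffold graph construction: pair geometry, edge aggregation, support
filtering, repeat flagging, and the pair-accounting invariant."""

from __future__ import annotations

import random

import pytest

from hapscaffold.formats import AlignmentSet, PairStatus, ReadAlignment
from hapscaffold.graph import (
    ContigEnd,
    End,
    PairLink,
    Reject,
    SamePlacement,
    apply_min_support,
    build_graph,
    flag_repeats,
    pair_to_edge,
)

LENGTHS = {"c1": 1000, "c2": 1000, "c3": 1000}


def aln(rid, cid, start, end, strand):
    return ReadAlignment(rid, cid, start, end, strand)


# ---------------------------------------------------------------------------
# pair_to_edge


def test_innie_pair_links_3p_to_5p_with_tail_arithmetic():
    # read1 forward on c1, 150 bp from read start to c1's 3' terminus
    a1 = aln("p/1", "c1", 850, 925, "+")
    # read2 reverse on c2, 150 bp from read end back to c2's 5' terminus
    a2 = aln("p/2", "c2", 75, 150, "-")
    out = pair_to_edge(a1, a2, 400, LENGTHS)
    assert isinstance(out, PairLink)
    assert out.end_a == ContigEnd("c1", End.THREE)
    assert out.end_b == ContigEnd("c2", End.FIVE)
    assert out.gap == 400 - 150 - 150 == 100


def test_negative_gap_means_contig_overlap():
    a1 = aln("p/1", "c1", 750, 825, "+")  # tail 250
    a2 = aln("p/2", "c2", 175, 250, "-")  # tail 250
    out = pair_to_edge(a1, a2, 400, LENGTHS)
    assert out.gap == -100


def test_same_contig_geometry():
    ok = pair_to_edge(aln("p/1", "c3", 100, 175, "+"), aln("p/2", "c3", 275, 350, "-"), 400, LENGTHS)
    assert ok == SamePlacement("c3", 250)
    bad = pair_to_edge(aln("p/1", "c3", 100, 175, "+"), aln("p/2", "c3", 275, 350, "+"), 400, LENGTHS)
    assert isinstance(bad, Reject)
    outie = pair_to_edge(aln("p/1", "c3", 275, 350, "+"), aln("p/2", "c3", 100, 175, "-"), 400, LENGTHS)
    assert isinstance(outie, Reject)


# ---------------------------------------------------------------------------
# build_graph


def test_concordant_pairs_aggregate_weight_and_mean_gap():
    alns = [
        aln("p1/1", "c1", 850, 925, "+"), aln("p1/2", "c2", 75, 150, "-"),   # gap 100
        aln("p2/1", "c1", 870, 945, "+"), aln("p2/2", "c2", 85, 160, "-"),   # gap 400-130-160=110...
    ]
    # recompute: p2 tails: c1: 1000-870=130 ; c2: end=160 -> gap=400-130-160=110? choose to make 120:
    alns[2] = aln("p2/1", "c1", 880, 955, "+")  # tail 120
    alns[3] = aln("p2/2", "c2", 85, 160, "-")   # tail 160 -> gap 120
    g, st = build_graph(alns, 400, LENGTHS)
    edges = list(g.all_edges())
    assert len(edges) == 1
    assert edges[0].weight == 2
    assert edges[0].gap_estimate == pytest.approx(110)
    assert [s.status for s in st] == [PairStatus.LINK, PairStatus.LINK]


def test_edge_identity_includes_end_tags():
    alns = [
        aln("p1/1", "c1", 850, 925, "+"), aln("p1/2", "c2", 75, 150, "-"),   # (c1:3p, c2:5p)
        aln("p2/1", "c1", 850, 925, "+"), aln("p2/2", "c2", 850, 925, "+"),  # (c1:3p, c2:3p)
    ]
    g, _ = build_graph(alns, 400, LENGTHS)
    assert sorted(e.weight for e in g.all_edges()) == [1, 1]


def test_multimapped_pair_suppressed_by_default():
    alns = [
        aln("p1/1", "c1", 0, 75, "+"),
        aln("p1/1", "c2", 0, 75, "+"),
        aln("p1/1", "c3", 0, 75, "+"),
        aln("p1/2", "c2", 500, 575, "-"),
    ]
    g, st = build_graph(AlignmentSet(alns), 400, LENGTHS)
    assert len(list(g.all_edges())) == 0
    assert st[0].status == PairStatus.MULTIPLY_MAPPED_SUPPRESSED
    g2, st2 = build_graph(AlignmentSet([ReadAlignment(a.read_id, a.contig_id, a.start, a.end, a.strand) for a in alns]), 400, LENGTHS, allow_multimapped=True)
    assert len(list(g2.all_edges())) >= 1


def test_unmapped_statuses(tmp_path):
    alns = AlignmentSet([aln("p1/1", "c1", 0, 75, "+")], unmapped_read_ids={"p1/2", "p2/1", "p2/2"})
    _, st = build_graph(alns, 400, LENGTHS)
    by = {s.pair_id: s.status for s in st}
    assert by["p1"] == PairStatus.ONE_END_UNMAPPED
    assert by["p2"] == PairStatus.BOTH_UNMAPPED


def test_repeat_contig_pairs_excluded():
    alns = [aln("p1/1", "c1", 850, 925, "+"), aln("p1/2", "c2", 75, 150, "-")]
    g, st = build_graph(alns, 400, LENGTHS, repeat_contigs={"c2"})
    assert len(list(g.all_edges())) == 0
    assert st[0].status == PairStatus.REPEAT_EXCLUDED


# ---------------------------------------------------------------------------
# min support


def test_min_support_boundaries():
    g, _ = build_graph(
        [
            aln("p1/1", "c1", 850, 925, "+"), aln("p1/2", "c2", 75, 150, "-"),
            aln("p2/1", "c1", 850, 925, "+"), aln("p2/2", "c2", 75, 150, "-"),
            aln("p3/1", "c1", 75, 150, "-"), aln("p3/2", "c3", 850, 925, "+"),
        ],
        400,
        LENGTHS,
    )
    apply_min_support(g, 2)
    active = list(g.active_edges())
    assert len(active) == 1 and active[0].weight == 2  # weight-2 edge retained
    assert len(list(g.excluded_edges())) == 1  # weight-1 edge excluded
    apply_min_support(g, 1)
    assert len(list(g.active_edges())) == 2  # no-op threshold
    with pytest.raises(ValueError):
        apply_min_support(g, 0)


# ---------------------------------------------------------------------------
# repeat flagging


def _star_graph():
    """hub with degree 12, everything else degree <= 2."""
    from hapscaffold.graph import ScaffoldGraph

    lengths = {f"s{i:02d}": 500 for i in range(13)}
    lengths["hub"] = 500
    g = ScaffoldGraph(lengths)
    ids = sorted(set(lengths) - {"hub"})
    for i, cid in enumerate(ids[:12]):
        g.add_gap_sample(ContigEnd("hub", End.THREE if i % 2 else End.FIVE), ContigEnd(cid, End.FIVE), 10)
    for a, b in zip(ids, ids[1:]):
        g.add_gap_sample(ContigEnd(a, End.THREE), ContigEnd(b, End.FIVE), 10)
    return g


def test_degree_outlier_flagged():
    g = _star_graph()
    flagged = flag_repeats(g, degree_factor=3.0)
    assert flagged == {"hub"}


def test_uniform_degrees_not_flagged():
    from hapscaffold.graph import ScaffoldGraph

    g = ScaffoldGraph({"a": 500, "b": 500, "c": 500})
    g.add_gap_sample(ContigEnd("a", End.THREE), ContigEnd("b", End.FIVE), 10)
    g.add_gap_sample(ContigEnd("b", End.THREE), ContigEnd("c", End.FIVE), 10)
    assert flag_repeats(g, degree_factor=3.0) == set()


def test_depth_outlier_flagged_against_mode():
    from hapscaffold.graph import ScaffoldGraph

    lengths = {f"x{i}": 500 for i in range(6)}
    g = ScaffoldGraph(lengths)
    depths = {"x0": 80, "x1": 80, "x2": 80, "x3": 81, "x4": 79, "x5": 240}
    flagged = flag_repeats(g, depth_table=depths, depth_factor=2.0)
    assert flagged == {"x5"}


# ---------------------------------------------------------------------------
# conservation + symmetry invariants


def _random_pairs(rng, n_pairs):
    """Random synthetic pairs over a small contig panel, including unmapped,
    multimapped, same-contig, and cross-contig cases."""
    alns, unmapped = [], set()
    for i in range(n_pairs):
        pid = f"p{i:04d}"
        for mate in (1, 2):
            rid = f"{pid}/{mate}"
            kind = rng.random()
            if kind < 0.08:
                unmapped.add(rid)
                continue
            n_hits = 2 if kind < 0.15 else 1
            for _ in range(n_hits):
                cid = rng.choice(sorted(LENGTHS))
                start = rng.randrange(0, LENGTHS[cid] - 75)
                alns.append(aln(rid, cid, start, start + 75, rng.choice("+-")))
    return AlignmentSet(alns, unmapped)


def test_pair_accounting_conservation_1000_pairs():
    rng = random.Random(42)
    aset = _random_pairs(rng, 1000)
    g, st = build_graph(aset, 400, LENGTHS)
    assert len(st) == 1000  # exactly one status per pair
    n_link = sum(1 for s in st if s.status == PairStatus.LINK)
    assert sum(e.weight for e in g.all_edges()) == n_link
    assert sum(1 for s in st) == 1000


def test_build_graph_invariant_under_mate_order_swap():
    rng = random.Random(7)
    aset = _random_pairs(rng, 200)
    swapped = [
        ReadAlignment(
            a.read_id.rsplit("/", 1)[0] + "/" + ("2" if a.mate == 1 else "1"),
            a.contig_id, a.start, a.end, a.strand,
        )
        for a in aset.alignments
    ]
    g1, st1 = build_graph(aset, 400, LENGTHS)
    g2, st2 = build_graph(AlignmentSet(swapped, set(aset.unmapped_read_ids)), 400, LENGTHS)
    e1 = {e.key: (e.weight, round(e.gap_estimate, 6)) for e in g1.all_edges()}
    e2 = {e.key: (e.weight, round(e.gap_estimate, 6)) for e in g2.all_edges()}
    assert e1 == e2
    assert [s.status for s in st1] == [s.status for s in st2]


def test_edge_weights_match_direct_tally_of_pair_outcomes():
    """Brute-force equivalence on <= 100 pairs."""
    rng = random.Random(3)
    aset = _random_pairs(rng, 100)
    g, _ = build_graph(aset, 400, LENGTHS)
    from collections import Counter

    from hapscaffold.graph import edge_key, group_pairs

    tally = Counter()
    for pid, (p1, p2) in group_pairs(aset).items():
        if len(p1) == 1 and len(p2) == 1:
            out = pair_to_edge(p1[0], p2[0], 400, LENGTHS)
            if isinstance(out, PairLink):
                tally[edge_key(out.end_a, out.end_b)] += 1
    assert {e.key: e.weight for e in g.all_edges()} == dict(tally)


def test_gap_estimate_exact_in_error_free_regime_and_shrinks_with_weight():
    """With exact inserts the estimate equals the true gap; with jitter the
    error shrinks as support grows."""
    import statistics

    rng = random.Random(5)
    true_gap = 120

    def make_graph(n_pairs, sd):
        alns = []
        for i in range(n_pairs):
            insert = 400 + (round(rng.gauss(0, sd)) if sd else 0)
            tail1 = rng.randrange(76, 140)
            tail2 = insert - tail1 - true_gap
            alns.append(aln(f"p{i}/1", "c1", 1000 - tail1, 1000 - tail1 + 75, "+"))
            alns.append(aln(f"p{i}/2", "c2", tail2 - 75, tail2, "-"))
        g, _ = build_graph(alns, 400, LENGTHS)
        (edge,) = g.all_edges()
        return edge

    assert make_graph(20, 0).gap_estimate == pytest.approx(true_gap)
    errors_small = [abs(make_graph(4, 30).gap_estimate - true_gap) for _ in range(30)]
    errors_big = [abs(make_graph(64, 30).gap_estimate - true_gap) for _ in range(30)]
    assert statistics.mean(errors_big) < statistics.mean(errors_small)
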