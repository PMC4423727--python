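"""Detection of heterozygous bubbles in the scaffold graph.

A *perfect bubble* is the motif (c1) = a|b = (c2): two candidate homologous
contigs ``a`` and ``b``, each with a single conflict-free scaffolding to a
common flanking contig ``c1`` on one side and to a different common contig
``c2`` on the other, with both flanks attaching ``a`` and ``b`` through the
same contig end (consistent orientation) and carrying no other edge on that
end. Perfect bubbles are the training source for the homolog classifier.

Imperfect bubbles — candidate 4-tuples with missing or conflicting edges,
or with one flank absent entirely — are enumerated and ranked by a
lexicographic perfectness score so the classifier can vet them in
decreasing order of topological support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .graph import ContigEnd, End, EdgeKey, ScaffoldGraph


@dataclass(frozen=True, slots=True)
class PerfectnessScore:
    missing_edges: int
    conflict_count: int
    total_support: int

    @property
    def perfect(self) -> bool:
        return self.missing_edges == 0 and self.conflict_count == 0

    @property
    def sort_key(self) -> tuple:
        # fewer missing < fewer conflicts < higher support
        return (self.missing_edges, self.conflict_count, -self.total_support)


@dataclass(frozen=True, slots=True)
class Bubble:
    """(c1) = a|b = (c2) with its up-to-four edges.

    ``a < b`` lexicographically (unordered pair, canonicalized); ``c2`` may
    be None for a partial (one-flank) candidate. Edge fields hold graph edge
    keys or None when the edge is absent."""

    c1: Optional[str]
    a: str
    b: str
    c2: Optional[str]
    e_c1a: Optional[EdgeKey]
    e_c1b: Optional[EdgeKey]
    e_ac2: Optional[EdgeKey]
    e_bc2: Optional[EdgeKey]

    @property
    def heterotigs(self) -> tuple[str, str]:
        return (self.a, self.b)

    @property
    def flanks(self) -> tuple[str, ...]:
        return tuple(c for c in (self.c1, self.c2) if c is not None)

    @property
    def edges(self) -> tuple[EdgeKey, ...]:
        return tuple(e for e in (self.e_c1a, self.e_c1b, self.e_ac2, self.e_bc2) if e is not None)

    def edges_for_het(self, het: str) -> tuple[Optional[EdgeKey], Optional[EdgeKey]]:
        """(c1-side edge, c2-side edge) for one heterotig."""
        if het == self.a:
            return (self.e_c1a, self.e_ac2)
        if het == self.b:
            return (self.e_c1b, self.e_bc2)
        raise KeyError(het)

    @property
    def signature(self) -> tuple:
        return (frozenset((self.a, self.b)), frozenset(f for f in (self.c1, self.c2) if f))


def make_bubble(
    c1: Optional[str],
    a: str,
    b: str,
    c2: Optional[str],
    e_c1a, e_c1b, e_ac2, e_bc2,
) -> Bubble:
    """Canonicalize so that a < b and, for full bubbles, c1 <= c2 ... the
    flank order is kept as given (c1 = the shared 5'-side seed) except that
    swapping a/b swaps the per-heterotig edges accordingly."""
    if b < a:
        a, b = b, a
        e_c1a, e_c1b = e_c1b, e_c1a
        e_ac2, e_bc2 = e_bc2, e_ac2
    if c1 is None and c2 is not None:
        c1, c2 = c2, c1
        e_c1a, e_ac2 = e_ac2, e_c1a
        e_c1b, e_bc2 = e_bc2, e_c1b
    elif c1 is not None and c2 is not None and c2 < c1:
        c1, c2 = c2, c1
        e_c1a, e_ac2 = e_ac2, e_c1a
        e_c1b, e_bc2 = e_bc2, e_c1b
    return Bubble(c1, a, b, c2, e_c1a, e_c1b, e_ac2, e_bc2)


def _single_active_edge(graph: ScaffoldGraph, ce: ContigEnd):
    edges = graph.edges_at(ce)
    if len(edges) != 1:
        return None
    return edges[0]


def find_perfect_bubbles(graph: ScaffoldGraph) -> list[Bubble]:
    """Every perfect bubble in the (support-filtered) graph.

    Repeat-flagged contigs cannot take part. Output is deterministic:
    sorted by (a, b). Two perfect bubbles may share a flanking contig but
    can never share a heterotig (each heterotig end carries exactly one
    edge, so membership in two bubbles is impossible)."""
    bubbles: dict[tuple, Bubble] = {}
    repeat = graph.repeat_flags

    for a in sorted(graph.contig_lengths):
        if a in repeat:
            continue
        e5 = _single_active_edge(graph, ContigEnd(a, End.FIVE))
        e3 = _single_active_edge(graph, ContigEnd(a, End.THREE))
        if e5 is None or e3 is None:
            continue
        c1_end = e5.other(a)
        c2_end = e3.other(a)
        c1, c2 = c1_end.contig_id, c2_end.contig_id
        if c1 == c2 or a in (c1, c2) or c1 in repeat or c2 in repeat:
            continue
        # flank ends must carry exactly the two bubble edges (no conflicts)
        c1_edges = graph.edges_at(c1_end)
        c2_edges = graph.edges_at(c2_end)
        if len(c1_edges) != 2 or len(c2_edges) != 2:
            continue
        partners1 = {e.other(c1).contig_id for e in c1_edges} - {a}
        partners2 = {e.other(c2).contig_id for e in c2_edges} - {a}
        if len(partners1) != 1 or partners1 != partners2:
            continue
        b = next(iter(partners1))
        if b == a or b in (c1, c2) or b in repeat:
            continue
        e_c1b = next(e for e in c1_edges if e.other(c1).contig_id == b)
        e_bc2 = next(e for e in c2_edges if e.other(c2).contig_id == b)
        # b's two attachments must sit on opposite ends of b, each being
        # b's single candidate scaffolding in that direction
        b_end1 = e_c1b.other(c1)
        b_end2 = e_bc2.other(c2)
        if b_end1.contig_id != b or b_end2.contig_id != b or b_end1.end == b_end2.end:
            continue
        if len(graph.edges_at(b_end1)) != 1 or len(graph.edges_at(b_end2)) != 1:
            continue
        bub = make_bubble(c1, a, b, c2, e5.key, e_c1b.key, e3.key, e_bc2.key)
        bubbles[bub.signature] = bub

    return sorted(bubbles.values(), key=lambda bb: (bb.a, bb.b))


def _conflicts_at(graph: ScaffoldGraph, ce: ContigEnd, own: set[EdgeKey]) -> int:
    return sum(1 for e in graph.edges_at(ce) if e.key not in own)


def score_candidate(graph: ScaffoldGraph, bubble: Bubble) -> PerfectnessScore:
    """Perfectness of a candidate: missing edges among the four, conflicting
    (non-bubble) active edges on every end the bubble touches, and the total
    support of its present edges."""
    own = set(bubble.edges)
    present = len(own)
    missing = 4 - present

    ends: set[ContigEnd] = set()
    for key in own:
        ends.update(key)
    # the far ends of a and b count even when their flank edge is missing:
    # an edge elsewhere on that end conflicts with completing the bubble
    for het in bubble.heterotigs:
        for end in (End.FIVE, End.THREE):
            ce = ContigEnd(het, end)
            if graph.edges_at(ce):
                ends.add(ce)
    conflicts = sum(_conflicts_at(graph, ce, own) for ce in sorted(ends))
    support = sum(graph.edge(k).weight for k in own)
    return PerfectnessScore(missing, conflicts, support)


def enumerate_imperfect_bubbles(
    graph: ScaffoldGraph,
    perfect: Iterable[Bubble],
    *,
    min_present_edges: int = 2,
    allow_partial_flank: bool = True,
) -> list[tuple[Bubble, PerfectnessScore]]:
    """Candidate bubbles that fail perfection, best first.

    Candidates are seeded from every contig end carrying two or more edges
    (a shared flank with consistent orientation); the opposite flank is
    searched among the partners of the heterotigs' far ends, or recorded as
    absent (a partial, one-flank candidate) when permitted. Candidates with
    fewer than ``min_present_edges`` of the four edges are dropped, as are
    exact duplicates of perfect bubbles."""
    repeat = graph.repeat_flags
    perfect_sigs = {b.signature for b in perfect}
    seen: dict[tuple, tuple[Bubble, PerfectnessScore]] = {}

    for c1 in sorted(graph.contig_lengths):
        if c1 in repeat:
            continue
        for flank_end in (End.FIVE, End.THREE):
            ce = ContigEnd(c1, flank_end)
            edges_here = graph.edges_at(ce)
            if len(edges_here) < 2:
                continue
            partner_edges: dict[str, list] = {}
            for e in edges_here:
                other = e.other(c1)
                if other.contig_id not in repeat and other.contig_id != c1:
                    partner_edges.setdefault(other.contig_id, []).append(e)
            names = sorted(partner_edges)
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    e_c1a = partner_edges[a][0]
                    e_c1b = partner_edges[b][0]
                    a_far = ContigEnd(a, e_c1a.other(c1).end.opposite())
                    b_far = ContigEnd(b, e_c1b.other(c1).end.opposite())
                    c2_candidates: set[str] = set()
                    for far in (a_far, b_far):
                        for e in graph.edges_at(far):
                            cid = e.other(far.contig_id).contig_id
                            if cid not in (c1, a, b) and cid not in repeat:
                                c2_candidates.add(cid)

                    def add(bub: Bubble) -> None:
                        sig = bub.signature
                        if sig in perfect_sigs or sig in seen:
                            return
                        seen[sig] = (bub, score_candidate(graph, bub))

                    for c2 in sorted(c2_candidates):
                        e_ac2 = next(
                            (e for e in graph.edges_at(a_far) if e.other(a).contig_id == c2),
                            None,
                        )
                        e_bc2 = next(
                            (e for e in graph.edges_at(b_far) if e.other(b).contig_id == c2),
                            None,
                        )
                        present = 2 + (e_ac2 is not None) + (e_bc2 is not None)
                        if present < min_present_edges:
                            continue
                        add(
                            make_bubble(
                                c1, a, b, c2,
                                e_c1a.key, e_c1b.key,
                                e_ac2.key if e_ac2 else None,
                                e_bc2.key if e_bc2 else None,
                            )
                        )
                    if allow_partial_flank and (not c2_candidates) and min_present_edges <= 2:
                        add(make_bubble(c1, a, b, None, e_c1a.key, e_c1b.key, None, None))

    ranked = sorted(
        seen.values(),
        key=lambda t: (t[1].sort_key, (t[0].c1 or "", t[0].a, t[0].b, t[0].c2 or "")),
    )
    return ranked
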