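"""Bubble acceptance, greedy chain linking, phasing, and haplotype output.

The included-edge set grows monotonically under two rules:

* a candidate bubble is accepted only if none of its edges is already
  included, none of the contig ends it touches is already occupied, and it
  does not close a cycle (its two flanks are not yet connected);
* a remaining edge is included greedily (descending weight) only if both of
  its contig ends are free and it does not close a cycle.

An accepted homolotig pair is one *slot*; the included subgraph is then a
disjoint union of simple slot paths — bubble chains. Within each chain,
read pairs whose two ends map to heterotigs of different bubbles vote for
placing those heterotigs on the same haplotype; a greedy majority-vote
2-coloring along the chain yields complementary phase groups, and the two
linear haploid scaffolds per chain are emitted with gaps rendered as runs
of N.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .bubbles import Bubble
from .formats import ContigRecord
from .graph import ContigEnd, End, EdgeKey, ScaffoldGraph

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_away(x: float) -> int:
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


# ---------------------------------------------------------------------------
# Included edge set


class IncludedEdgeSet:
    """Edges selected so far, with per-contig-end occupancy and a union-find
    over slots (an accepted homolotig pair counts as one slot) that keeps
    the included subgraph acyclic."""

    def __init__(self) -> None:
        self.edges: set[EdgeKey] = set()
        self.by_end: dict[ContigEnd, list[EdgeKey]] = {}
        self.edge_owner: dict[EdgeKey, Optional[Bubble]] = {}
        self.bubbles: list[Bubble] = []
        self.claimed_ends: set[ContigEnd] = set()
        self._parent: dict[str, str] = {}

    # union-find over contig ids ------------------------------------------

    def _find(self, cid: str) -> str:
        parent = self._parent
        root = cid
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(cid, cid) != root:
            cid, parent[cid] = parent[cid], root
        return root

    def _union(self, a: str, b: str) -> None:
        ra, rb = self._find(a), self._find(b)
        if ra != rb:
            self._parent[max(ra, rb)] = min(ra, rb)

    def connected(self, a: str, b: str) -> bool:
        return self._find(a) == self._find(b)

    # occupancy ------------------------------------------------------------

    def occupied(self, ce: ContigEnd) -> bool:
        return bool(self.by_end.get(ce)) or ce in self.claimed_ends

    def _add_edge(self, key: EdgeKey, owner: Optional[Bubble]) -> None:
        self.edges.add(key)
        self.edge_owner[key] = owner
        for ce in key:
            self.by_end.setdefault(ce, []).append(key)
        self._union(key[0].contig_id, key[1].contig_id)

    # bubbles ---------------------------------------------------------------

    def can_accept_bubble(self, bubble: Bubble) -> bool:
        keys = bubble.edges
        if any(k in self.edges for k in keys):
            return False
        touched = {ce for k in keys for ce in k}
        # all four heterotig ends are claimed by the bubble, present or not
        for het in bubble.heterotigs:
            touched.add(ContigEnd(het, End.FIVE))
            touched.add(ContigEnd(het, End.THREE))
        if any(self.occupied(ce) for ce in touched):
            return False
        if bubble.c1 is not None and bubble.c2 is not None:
            if self.connected(bubble.c1, bubble.c2):
                return False
        return True

    def accept_bubble(self, bubble: Bubble) -> None:
        assert self.can_accept_bubble(bubble)
        for key in bubble.edges:
            self._add_edge(key, bubble)
        # claim every heterotig end, including sides whose edge is missing,
        # so partial bubbles stay linear in the slot graph
        for het in bubble.heterotigs:
            for end in (End.FIVE, End.THREE):
                self.claimed_ends.add(ContigEnd(het, end))
        self._union(bubble.a, bubble.b)
        self.bubbles.append(bubble)

    # plain edges -----------------------------------------------------------

    def can_include_edge(self, key: EdgeKey) -> bool:
        if key in self.edges:
            return False
        if any(self.occupied(ce) for ce in key):
            return False
        return not self.connected(key[0].contig_id, key[1].contig_id)

    def include_edge(self, key: EdgeKey) -> None:
        assert self.can_include_edge(key)
        self._add_edge(key, None)

    # invariants -------------------------------------------------------------

    def assert_occupancy(self) -> None:
        """No contig end carries two included edges unless both belong to one
        bubble's shared flank."""
        for ce, keys in self.by_end.items():
            if len(keys) <= 1:
                continue
            owners = {id(self.edge_owner.get(k)) for k in keys}
            if len(keys) > 2 or len(owners) != 1 or self.edge_owner.get(keys[0]) is None:
                raise AssertionError(f"occupancy violated at {ce}: {keys}")

    def assert_bubble_purity(self) -> None:
        """Every included edge belongs to an accepted bubble (holds between
        bubble acceptance and greedy linking)."""
        for key in self.edges:
            if self.edge_owner.get(key) is None:
                raise AssertionError(f"non-bubble edge {key} in included set")


def accept_bubbles(
    perfect: Sequence[Bubble],
    classified_imperfect: Sequence[Bubble],
    included: IncludedEdgeSet,
) -> tuple[list[Bubble], list[Bubble]]:
    """Perfect bubbles first, then positively classified imperfect bubbles in
    decreasing perfectness order; a bubble touching any already-occupied end
    or reusing an included edge is disallowed. Returns (accepted, rejected)."""
    accepted: list[Bubble] = []
    rejected: list[Bubble] = []
    for bubble in (*perfect, *classified_imperfect):
        if included.can_accept_bubble(bubble):
            included.accept_bubble(bubble)
            accepted.append(bubble)
        else:
            rejected.append(bubble)
        included.assert_occupancy()
    return accepted, rejected


def greedy_link(
    graph: ScaffoldGraph,
    included: IncludedEdgeSet,
) -> list[EdgeKey]:
    """Include remaining edges of this rank's graph greedily.

    Edges are visited in descending weight (ties: lexicographically smaller
    canonical key, i.e. smaller partner contig id then end tag) and included
    iff neither contig end is occupied; repeat-flagged contigs are skipped."""
    added: list[EdgeKey] = []
    candidates = sorted(graph.active_edges(), key=lambda e: (-e.weight, e.key))
    for edge in candidates:
        if any(ce.contig_id in graph.repeat_flags for ce in edge.key):
            continue
        if included.can_include_edge(edge.key):
            included.include_edge(edge.key)
            added.append(edge.key)
            included.assert_occupancy()
    return added


# ---------------------------------------------------------------------------
# Chains


@dataclass(slots=True)
class MonoElement:
    contig: str
    orient: str  # "+" or "-"


@dataclass(slots=True)
class PairElement:
    bubble: Optional[Bubble]
    a: Optional[str]
    a_orient: str
    b: Optional[str]
    b_orient: str

    @property
    def heterotigs(self) -> tuple[str, ...]:
        return tuple(h for h in (self.a, self.b) if h is not None)


ChainElement = MonoElement | PairElement


@dataclass(slots=True)
class Chain:
    id: str
    elements: list[ChainElement]
    # boundary_gaps[i]: contig-pair -> gap between elements i and i+1
    boundary_gaps: list[dict[frozenset, float]]

    @property
    def contigs(self) -> list[str]:
        out: list[str] = []
        for el in self.elements:
            if isinstance(el, MonoElement):
                out.append(el.contig)
            else:
                out.extend(el.heterotigs)
        return out

    @property
    def pair_elements(self) -> list[PairElement]:
        return [el for el in self.elements if isinstance(el, PairElement)]


class _Slot:
    __slots__ = ("idx", "bubble", "contig", "ports")

    def __init__(self, idx: int, bubble: Optional[Bubble], contig: Optional[str]):
        self.idx = idx
        self.bubble = bubble
        self.contig = contig
        # port -> (neighbor slot idx, [edge keys])
        self.ports: dict[str, tuple[int, list[EdgeKey]]] = {}


def build_chains(
    included: IncludedEdgeSet,
    gaps: Mapping[EdgeKey, float],
) -> list[Chain]:
    """Assemble the included subgraph into ordered, oriented chains.

    ``gaps`` maps edge keys to gap estimates (edges may come from several
    rank graphs; missing keys default to 0).

    Each accepted homolotig pair is one slot with a left port (its c1-side
    edges) and a right port (c2 side); every other contig is a slot whose
    ports are its two ends. Occupancy and the union-find guarantee the slot
    graph is a disjoint union of simple paths."""
    slots: list[_Slot] = []
    slot_of: dict[str, int] = {}
    for bubble in included.bubbles:
        idx = len(slots)
        slots.append(_Slot(idx, bubble, None))
        for het in bubble.heterotigs:
            slot_of[het] = idx
    for key in sorted(included.edges):
        for ce in key:
            if ce.contig_id not in slot_of:
                idx = len(slots)
                slots.append(_Slot(idx, None, ce.contig_id))
                slot_of[ce.contig_id] = idx

    def port_of(slot: _Slot, ce: ContigEnd) -> str:
        if slot.bubble is None:
            return ce.end.value
        bub = slot.bubble
        left, right = bub.edges_for_het(ce.contig_id)
        if left is not None and ce in left:
            return "L"
        if right is not None and ce in right:
            return "R"
        # missing-edge side: the end not used by the present edge
        present = left or right
        used_end = next(e for e in present if e.contig_id == ce.contig_id)
        return "R" if port_of(slot, used_end) == "L" else "L"

    for key in sorted(included.edges):
        ce_a, ce_b = key
        sa, sb = slots[slot_of[ce_a.contig_id]], slots[slot_of[ce_b.contig_id]]
        pa, pb = port_of(sa, ce_a), port_of(sb, ce_b)
        for slot, port, other in ((sa, pa, sb.idx), (sb, pb, sa.idx)):
            if port in slot.ports:
                prev_idx, keys = slot.ports[port]
                assert prev_idx == other, f"port {port} of slot {slot.idx} links two slots"
                keys.append(key)
            else:
                slot.ports[port] = (other, [key])

    # walk paths -------------------------------------------------------------
    visited: set[int] = set()
    chains: list[Chain] = []

    def slot_sort_key(slot: _Slot) -> str:
        return slot.contig if slot.contig else min(slot.bubble.heterotigs)

    endpoints = [s for s in slots if len(s.ports) <= 1 and s.ports]
    endpoints.sort(key=slot_sort_key)

    def orient_mono(contig: str, entry: Optional[ContigEnd], exit_: Optional[ContigEnd]) -> str:
        if entry is not None:
            return "+" if entry.end is End.FIVE else "-"
        assert exit_ is not None
        return "+" if exit_.end is End.THREE else "-"

    def het_orient(bub: Bubble, het: str, left_first: bool) -> str:
        left, right = bub.edges_for_het(het)
        if not left_first:
            left, right = right, left
        if left is not None:
            entry = next(ce for ce in left if ce.contig_id == het)
            return "+" if entry.end is End.FIVE else "-"
        exit_ = next(ce for ce in right if ce.contig_id == het)
        return "+" if exit_.end is End.THREE else "-"

    for start in endpoints:
        if start.idx in visited:
            continue
        elements: list[ChainElement] = []
        boundary_gaps: list[dict[frozenset, float]] = []
        prev_idx = -1
        cur = start
        entry_port: Optional[str] = None
        while True:
            visited.add(cur.idx)
            exit_ports = [p for p in cur.ports if p != entry_port]
            exit_port = exit_ports[0] if exit_ports else None
            if cur.bubble is None:
                entry_ce = ContigEnd(cur.contig, End(entry_port)) if entry_port else None
                exit_ce = ContigEnd(cur.contig, End(exit_port)) if exit_port else None
                elements.append(MonoElement(cur.contig, orient_mono(cur.contig, entry_ce, exit_ce)))
            else:
                left_first = (entry_port or ("L" if exit_port == "R" else "R")) == "L"
                bub = cur.bubble
                elements.append(
                    PairElement(
                        bub,
                        bub.a,
                        het_orient(bub, bub.a, left_first),
                        bub.b,
                        het_orient(bub, bub.b, left_first),
                    )
                )
            if exit_port is None:
                break
            nxt_idx, keys = cur.ports[exit_port]
            gapmap: dict[frozenset, float] = {}
            for key in keys:
                gapmap[frozenset(ce.contig_id for ce in key)] = gaps.get(key, 0.0)
            boundary_gaps.append(gapmap)
            nxt = slots[nxt_idx]
            # which port of nxt received this link
            entry_port = next(p for p, (o, _) in nxt.ports.items() if o == cur.idx)
            prev_idx, cur = cur.idx, nxt

        if len(elements) >= 2:
            chains.append(Chain(f"chain{len(chains):05d}", elements, boundary_gaps))

    # renumber deterministically by first contig id
    chains.sort(key=lambda c: c.contigs[0])
    for i, chain in enumerate(chains):
        chain.id = f"scaffold{i + 1:05d}"
    return chains


# ---------------------------------------------------------------------------
# Phasing


@dataclass(slots=True)
class PhaseGroup:
    id: str
    members: list[str]
    complement_id: str
    chain_id: str


def phase_chains(
    chains: Sequence[Chain],
    het_links: Mapping[frozenset, int],
) -> tuple[list[PhaseGroup], dict[str, int], int]:
    """Two-color heterotigs along each chain by majority vote.

    ``het_links[{x, y}]`` is the number of read pairs linking heterotigs x
    and y; such a link votes for placing x and y on the same haplotype.
    Bubbles are visited in chain order; a bubble with no linking evidence to
    the currently open group pair closes it and starts a new complementary
    pair. Returns (phase groups, coloring contig -> 1|2, conflicting-vote
    count)."""
    groups: list[PhaseGroup] = []
    coloring: dict[str, int] = {}
    conflicts = 0

    def weight(x: Optional[str], y: str) -> int:
        if x is None:
            return 0
        return het_links.get(frozenset((x, y)), 0)

    for chain in chains:
        g1: list[str] = []
        g2: list[str] = []

        def close() -> None:
            nonlocal g1, g2
            if not g1 and not g2:
                return
            id1 = f"pg{len(groups) + 1:05d}"
            id2 = f"pg{len(groups) + 2:05d}"
            groups.append(PhaseGroup(id1, list(g1), id2, chain.id))
            groups.append(PhaseGroup(id2, list(g2), id1, chain.id))
            g1, g2 = [], []

        for el in chain.pair_elements:
            a, b = el.a, el.b
            if a is not None and b is not None and b < a:
                a, b = b, a
            same = sum(weight(a, x) for x in g1) + sum(weight(b, x) for x in g2)
            opp = sum(weight(a, x) for x in g2) + sum(weight(b, x) for x in g1)
            if not g1 and not g2:
                pass  # first bubble of the chain starts the group pair
            elif same + opp == 0:
                close()
            if min(same, opp) > 0:
                conflicts += min(same, opp)
            if same < opp:
                a, b = b, a
            if a is not None:
                g1.append(a)
                coloring[a] = 1
            if b is not None:
                g2.append(b)
                coloring[b] = 2
        close()

    if conflicts:
        logger.info("phasing resolved %d conflicting link votes by majority", conflicts)
    return groups, coloring, conflicts


# ---------------------------------------------------------------------------
# Haploid scaffold emission


def _oriented(seq: str, orient: str) -> str:
    return seq if orient == "+" else revcomp(seq)


def _het_for_hap(
    el: PairElement, coloring: Mapping[str, int], hap_no: int
) -> tuple[Optional[str], str]:
    """The heterotig (and orientation) a pair element contributes to one
    haplotype. Uncolored pairs fall back to the deterministic convention:
    lexicographically smaller id -> hap1."""
    hets = [(h, o) for h, o in ((el.a, el.a_orient), (el.b, el.b_orient)) if h is not None]
    colors = [coloring.get(h) for h, _ in hets]
    if len(hets) == 2 and colors[0] is not None and colors[1] is not None and colors[0] != colors[1]:
        for (h, o), c in zip(hets, colors):
            if c == hap_no:
                return h, o
        return None, "+"
    # fallback: smaller id (hets are already sorted a < b) -> hap1
    idx = hap_no - 1
    if idx < len(hets):
        return hets[idx]
    return None, "+"


def emit_haplotypes(
    chains: Sequence[Chain],
    coloring: Mapping[str, int],
    contig_set: Mapping[str, ContigRecord],
    gap_floor: int = 10,
    singletons: Iterable[str] = (),
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], list[tuple]]:
    """Render each chain as two linear haploid sequences.

    hap1 carries homotigs plus color-1 heterotigs, hap2 the complementary
    set; inter-contig gaps become N-runs of max(round(gap), gap_floor)
    (rounding half away from zero). A bubble with a single heterotig
    contributes an N-run of that heterotig's length to the other haplotype.
    Singleton contigs are emitted identically in both outputs. Returns
    (hap1 records, hap2 records, AGP-like rows)."""
    hap1: list[tuple[str, str]] = []
    hap2: list[tuple[str, str]] = []
    agp: list[tuple] = []

    def gap_run(gap: float) -> str:
        return "N" * max(round_half_away(gap), gap_floor)

    for chain in chains:
        for hap_no, out in ((1, hap1), (2, hap2)):
            parts: list[str] = []
            prev_contig: Optional[str] = None
            for i, el in enumerate(chain.elements):
                if isinstance(el, MonoElement):
                    contig, orient = el.contig, el.orient
                else:
                    contig, orient = _het_for_hap(el, coloring, hap_no)
                    if contig is None:
                        # partial pair: this haplotype gets a placeholder gap
                        other = el.a or el.b
                        parts.append("N" * contig_set[other].length)
                        agp.append((chain.id, hap_no, i, "gap_placeholder", contig_set[other].length))
                        prev_contig = None
                        if i < len(chain.boundary_gaps):
                            gaps = chain.boundary_gaps[i]
                            mean_gap = sum(gaps.values()) / len(gaps) if gaps else 0.0
                            parts.append(gap_run(mean_gap))
                        continue
                parts.append(_oriented(contig_set[contig].sequence, orient))
                agp.append((chain.id, hap_no, i, contig, orient))
                prev_contig = contig
                if i < len(chain.boundary_gaps):
                    gaps = chain.boundary_gaps[i]
                    nxt = chain.elements[i + 1]
                    gap = None
                    if prev_contig is not None:
                        nxt_contigs = (
                            [nxt.contig]
                            if isinstance(nxt, MonoElement)
                            else list(nxt.heterotigs)
                        )
                        for nc in nxt_contigs:
                            gap = gaps.get(frozenset((prev_contig, nc)), gap)
                            if frozenset((prev_contig, nc)) in gaps and coloring.get(nc, hap_no) == hap_no:
                                gap = gaps[frozenset((prev_contig, nc))]
                                break
                    if gap is None:
                        gap = sum(gaps.values()) / len(gaps) if gaps else 0.0
                    parts.append(gap_run(gap))
            out.append((f"{chain.id}_hap{hap_no}", "".join(parts)))

    for n, contig in enumerate(sorted(singletons), start=len(chains) + 1):
        sid = f"scaffold{n:05d}"
        seq = contig_set[contig].sequence
        hap1.append((f"{sid}_hap1", seq))
        hap2.append((f"{sid}_hap2", seq))
        agp.append((sid, 0, 0, contig, "+"))
    return hap1, hap2, agp
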