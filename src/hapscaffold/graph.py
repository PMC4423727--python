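"""The weighted bidirected scaffold graph.

Each vertex is a contig; each edge joins two *contig ends* (5' or 3'),
thereby fixing the relative orientation of both contigs and carrying a
support weight (number of concordant pairs) and a mean gap estimate.

End nomination convention (standard innie paired-end geometry): a read
aligned on the forward strand of a contig points off the contig's 3' end,
so its mate's contig is attached there; a reverse-strand read points off
the 5' end. The gap suggested by one pair is

    gap = mean_insert - tail_1 - tail_2

where tail is the distance from the alignment's outer read edge to the
nominated contig end (this includes the read length itself). Negative gaps
(overlapping contigs) are retained.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, NamedTuple

from .formats import (
    AlignmentSet,
    PairStatus,
    PairStatusRecord,
    ReadAlignment,
)


class End(str, Enum):
    FIVE = "5p"
    THREE = "3p"

    def opposite(self) -> "End":
        return End.THREE if self is End.FIVE else End.FIVE


class ContigEnd(NamedTuple):
    contig_id: str
    end: End


EdgeKey = tuple[ContigEnd, ContigEnd]


def edge_key(a: ContigEnd, b: ContigEnd) -> EdgeKey:
    """Canonical (sorted) identity of a bidirected edge."""
    return (a, b) if a <= b else (b, a)


@dataclass(slots=True)
class ScaffoldEdge:
    """A bidirected link between two contig ends.

    weight == number of supporting pairs == len(gap_samples);
    gap_estimate == arithmetic mean of the per-pair gap suggestions."""

    end_a: ContigEnd
    end_b: ContigEnd
    gap_samples: list[float] = field(default_factory=list)

    @property
    def key(self) -> EdgeKey:
        return edge_key(self.end_a, self.end_b)

    @property
    def weight(self) -> int:
        return len(self.gap_samples)

    @property
    def gap_estimate(self) -> float:
        return sum(self.gap_samples) / len(self.gap_samples)

    def other(self, contig_id: str) -> ContigEnd:
        if self.end_a.contig_id == contig_id:
            return self.end_b
        return self.end_a

    def end_of(self, contig_id: str) -> ContigEnd:
        if self.end_a.contig_id == contig_id:
            return self.end_a
        if self.end_b.contig_id == contig_id:
            return self.end_b
        raise KeyError(contig_id)


class ScaffoldGraph:
    """Contigs plus bidirected, end-tagged, weighted scaffolding edges.

    ``min_support`` (set via :func:`apply_min_support`) marks lighter edges
    nonexistent for every downstream query while retaining them for DOT
    rendering of excluded edges. ``repeat_flags`` holds contigs excluded
    from bubbles, chains and output."""

    def __init__(self, contig_lengths: dict[str, int]):
        self.contig_lengths = dict(contig_lengths)
        self.min_support = 1
        self.repeat_flags: set[str] = set()
        self._edges: dict[EdgeKey, ScaffoldEdge] = {}
        self._incident: dict[ContigEnd, set[EdgeKey]] = {}

    # construction -----------------------------------------------------

    def add_gap_sample(self, a: ContigEnd, b: ContigEnd, gap: float) -> ScaffoldEdge:
        if a.contig_id == b.contig_id:
            raise ValueError("self-links are not representable in the scaffold graph")
        key = edge_key(a, b)
        edge = self._edges.get(key)
        if edge is None:
            edge = ScaffoldEdge(*key)
            self._edges[key] = edge
            for ce in key:
                self._incident.setdefault(ce, set()).add(key)
        edge.gap_samples.append(gap)
        return edge

    # queries ------------------------------------------------------------

    def edge(self, key: EdgeKey) -> ScaffoldEdge:
        return self._edges[key]

    def has_edge(self, key: EdgeKey) -> bool:
        return key in self._edges

    def _is_active(self, key: EdgeKey) -> bool:
        return self._edges[key].weight >= self.min_support

    def edges_at(self, contig_end: ContigEnd, include_excluded: bool = False) -> list[ScaffoldEdge]:
        """Edges incident to one contig end (active only unless asked)."""
        keys = self._incident.get(contig_end, set())
        out = [
            self._edges[k]
            for k in keys
            if include_excluded or self._is_active(k)
        ]
        out.sort(key=lambda e: e.key)
        return out

    def degree(self, contig_id: str) -> int:
        """Number of distinct active edges touching either end of a contig."""
        keys: set[EdgeKey] = set()
        for end in (End.FIVE, End.THREE):
            keys |= {
                k
                for k in self._incident.get(ContigEnd(contig_id, end), set())
                if self._is_active(k)
            }
        return len(keys)

    def active_edges(self) -> Iterator[ScaffoldEdge]:
        return (e for k, e in self._edges.items() if self._is_active(k))

    def excluded_edges(self) -> Iterator[ScaffoldEdge]:
        return (e for k, e in self._edges.items() if not self._is_active(k))

    def all_edges(self) -> Iterator[ScaffoldEdge]:
        return iter(self._edges.values())

    def __len__(self) -> int:
        return len(self.contig_lengths)


# ---------------------------------------------------------------------------
# Pair geometry


@dataclass(frozen=True, slots=True)
class PairLink:
    end_a: ContigEnd
    end_b: ContigEnd
    gap: float


@dataclass(frozen=True, slots=True)
class SamePlacement:
    contig_id: str
    span: int


@dataclass(frozen=True, slots=True)
class Reject:
    reason: str


def _nominate(aln: ReadAlignment, contig_len: int) -> tuple[ContigEnd, int]:
    """The contig end the mate fragment extends toward, and the tail length
    from the alignment's outer read edge to that end (read length included)."""
    if aln.strand == "+":
        return ContigEnd(aln.contig_id, End.THREE), contig_len - aln.start
    return ContigEnd(aln.contig_id, End.FIVE), aln.end


def pair_to_edge(
    aln_1: ReadAlignment,
    aln_2: ReadAlignment,
    mean_insert: float,
    contig_lengths: dict[str, int],
) -> PairLink | SamePlacement | Reject:
    """Interpret one uniquely mapped pair as scaffolding evidence.

    Different contigs always yield a PairLink (each end nominates a contig
    end; the gap may be negative). Both ends on one contig yield
    SamePlacement when the innie geometry is consistent, else Reject."""
    if aln_1.contig_id != aln_2.contig_id:
        end_a, tail_a = _nominate(aln_1, contig_lengths[aln_1.contig_id])
        end_b, tail_b = _nominate(aln_2, contig_lengths[aln_2.contig_id])
        return PairLink(end_a, end_b, mean_insert - tail_a - tail_b)

    if aln_1.strand == aln_2.strand:
        return Reject("same-strand mates on one contig")
    fwd, rev = (aln_1, aln_2) if aln_1.strand == "+" else (aln_2, aln_1)
    if fwd.start > rev.start:
        return Reject("outward-facing mates on one contig")
    return SamePlacement(aln_1.contig_id, rev.end - fwd.start)


# ---------------------------------------------------------------------------
# Graph construction


def group_pairs(
    alignments: Iterable[ReadAlignment],
) -> dict[str, tuple[list[ReadAlignment], list[ReadAlignment]]]:
    """Group alignments by pair id into (mate-1 placements, mate-2 placements),
    preserving first-seen pair order."""
    pairs: dict[str, tuple[list[ReadAlignment], list[ReadAlignment]]] = {}
    for aln in alignments:
        slot = pairs.setdefault(aln.pair_id, ([], []))
        slot[aln.mate - 1].append(aln)
    return pairs


def build_graph(
    alignment_set: AlignmentSet | list[ReadAlignment],
    mean_insert: float,
    contig_lengths: dict[str, int],
    *,
    allow_multimapped: bool = False,
    repeat_contigs: frozenset[str] | set[str] = frozenset(),
) -> tuple[ScaffoldGraph, list[PairStatusRecord]]:
    """Aggregate paired-end evidence into a scaffold graph.

    Every input pair is classified into exactly one PairStatusRecord; the
    sum of edge weights plus non-LINK status counts equals the number of
    input pairs (when multi-mapping is suppressed, the default)."""
    graph = ScaffoldGraph(contig_lengths)
    statuses: list[PairStatusRecord] = []

    unmapped_ids: set[str] = set()
    if isinstance(alignment_set, AlignmentSet):
        unmapped_ids = alignment_set.unmapped_read_ids

    pairs = group_pairs(alignment_set)
    # pairs seen only as unmapped records
    for rid in sorted(unmapped_ids):
        pair_id = rid.rsplit("/", 1)[0]
        pairs.setdefault(pair_id, ([], []))

    _warn_short_insert(alignment_set, mean_insert)

    for pair_id, (p1, p2) in pairs.items():
        if not p1 and not p2:
            statuses.append(PairStatusRecord(pair_id, PairStatus.BOTH_UNMAPPED))
            continue
        if not p1 or not p2:
            present = p1 or p2
            statuses.append(
                PairStatusRecord(
                    pair_id,
                    PairStatus.ONE_END_UNMAPPED,
                    (present[0].contig_id,),
                )
            )
            continue
        if (len(p1) > 1 or len(p2) > 1) and not allow_multimapped:
            statuses.append(
                PairStatusRecord(
                    pair_id,
                    PairStatus.MULTIPLY_MAPPED_SUPPRESSED,
                    (str(len(p1)), str(len(p2))),
                )
            )
            continue
        if any(a.contig_id in repeat_contigs for a in (*p1, *p2)):
            statuses.append(
                PairStatusRecord(
                    pair_id,
                    PairStatus.REPEAT_EXCLUDED,
                    (p1[0].contig_id, p2[0].contig_id),
                )
            )
            continue

        outcomes = [
            pair_to_edge(a1, a2, mean_insert, contig_lengths)
            for a1 in p1
            for a2 in p2
        ]
        linked = False
        recorded = False
        for outcome in outcomes:
            if isinstance(outcome, PairLink):
                graph.add_gap_sample(outcome.end_a, outcome.end_b, outcome.gap)
                linked = True
        if linked:
            first = next(o for o in outcomes if isinstance(o, PairLink))
            statuses.append(
                PairStatusRecord(
                    pair_id,
                    PairStatus.LINK,
                    (first.end_a.contig_id, first.end_b.contig_id),
                )
            )
            recorded = True
        if not recorded:
            outcome = outcomes[0]
            if isinstance(outcome, SamePlacement):
                statuses.append(
                    PairStatusRecord(
                        pair_id,
                        PairStatus.SAME_CONTIG,
                        (outcome.contig_id, str(outcome.span)),
                    )
                )
            else:
                statuses.append(
                    PairStatusRecord(
                        pair_id, PairStatus.ORIENTATION_REJECTED, (outcome.reason,)
                    )
                )
    return graph, statuses


def _warn_short_insert(alignments: Iterable[ReadAlignment], mean_insert: float) -> None:
    for aln in alignments:
        read_len = aln.end - aln.start
        if mean_insert <= 2 * read_len:
            warnings.warn(
                f"mean insert {mean_insert:.0f} is not larger than twice the "
                f"read length ({read_len}); gap estimates will be unreliable",
                stacklevel=3,
            )
        break  # first mapped read is representative


def apply_min_support(graph: ScaffoldGraph, min_support: int = 2) -> ScaffoldGraph:
    """Mark edges below ``min_support`` nonexistent for downstream queries."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    graph.min_support = min_support
    return graph


def flag_repeats(
    graph: ScaffoldGraph,
    depth_table: dict[str, float] | None = None,
    degree_factor: float = 5.0,
    depth_factor: float = 3.0,
    min_len: int = 100,
    bin_width: float = 1.0,
) -> set[str]:
    """Flag repeat-like contigs by abnormal vertex degree or depth.

    A contig is flagged when its total active degree exceeds
    ``degree_factor`` times the median degree (median over contigs of at
    least ``min_len`` bases with at least one edge), or — when a depth table
    is supplied — when its depth exceeds ``depth_factor`` times the modal
    depth. Flagged contigs are excluded from bubbles, chains and output."""
    if degree_factor <= 0 or depth_factor <= 0:
        raise ValueError("factors must be > 0")
    flagged: set[str] = set()

    eligible = [c for c, ln in graph.contig_lengths.items() if ln >= min_len]
    degrees = {c: graph.degree(c) for c in eligible}
    linked = [d for d in degrees.values() if d > 0]
    if linked:
        median_degree = statistics.median(linked)
        if median_degree > 0:
            for cid, d in degrees.items():
                if d > degree_factor * median_degree:
                    flagged.add(cid)

    if depth_table:
        from .classify import depth_mode  # deferred: classify sits above graph

        modal = depth_mode(depth_table, bin_width=bin_width, contig_lengths=graph.contig_lengths, min_len=min_len)
        if modal > 0:
            for cid, depth in depth_table.items():
                if cid in graph.contig_lengths and graph.contig_lengths[cid] >= min_len and depth > depth_factor * modal:
                    flagged.add(cid)

    graph.repeat_flags |= flagged
    return flagged
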