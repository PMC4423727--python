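"""Independent oracles used by the test suite.

These deliberately re-derive results through different code paths than the
package: a literal scan over contig 4-tuples for perfect bubbles, and a
plain-Python dynamic-programming local aligner. They share only the
documented conventions (scores, tie-breaks), never the implementation.
"""

from __future__ import annotations

import random

from hapscaffold.graph import ContigEnd, End, ScaffoldGraph


# ---------------------------------------------------------------------------
# Perfect bubbles: literal 4-tuple scan


def brute_force_perfect_bubbles(graph: ScaffoldGraph) -> set[tuple]:
    """Apply the perfect-bubble definition verbatim over contig 4-tuples.

    Returns canonical signatures {(a,b) sorted, (c1,c2) sorted} so results
    can be compared with the package's finder irrespective of order."""
    ids = sorted(graph.contig_lengths)
    repeat = graph.repeat_flags

    def single_edge(cid: str, end: End):
        edges = graph.edges_at(ContigEnd(cid, end))
        return edges[0] if len(edges) == 1 else None

    found: set[tuple] = set()
    for a in ids:
        # a must have a single candidate scaffolding in each direction
        ea5 = single_edge(a, End.FIVE)
        ea3 = single_edge(a, End.THREE)
        if ea5 is None or ea3 is None or a in repeat:
            continue
        for b in ids:
            if b == a or b in repeat:
                continue
            for c1 in ids:
                for c2 in ids:
                    if len({a, b, c1, c2}) != 4:
                        continue
                    if c1 in repeat or c2 in repeat:
                        continue
                    if ea5.other(a).contig_id != c1 or ea3.other(a).contig_id != c2:
                        continue
                    # b: single scaffolding to c1 in either direction and to
                    # c2 in the opposite direction
                    ok_b = None
                    for end1, end2 in ((End.FIVE, End.THREE), (End.THREE, End.FIVE)):
                        eb1 = single_edge(b, end1)
                        eb2 = single_edge(b, end2)
                        if (
                            eb1 is not None
                            and eb2 is not None
                            and eb1.other(b).contig_id == c1
                            and eb2.other(b).contig_id == c2
                        ):
                            ok_b = (eb1, eb2)
                            break
                    if ok_b is None:
                        continue
                    eb1, eb2 = ok_b
                    # c1 and c2: identical orientation in both scaffoldings
                    # (same end used) and no conflicting scaffoldings there
                    c1_end_a = ea5.other(a)
                    c1_end_b = eb1.other(b)
                    c2_end_a = ea3.other(a)
                    c2_end_b = eb2.other(b)
                    if c1_end_a != c1_end_b or c2_end_a != c2_end_b:
                        continue
                    if len(graph.edges_at(c1_end_a)) != 2:
                        continue
                    if len(graph.edges_at(c2_end_a)) != 2:
                        continue
                    found.add(
                        (tuple(sorted((a, b))), tuple(sorted((c1, c2))))
                    )
    return found


def random_scaffold_graph(
    rng: random.Random, max_vertices: int = 25, max_edges: int = 60
) -> ScaffoldGraph:
    """A random end-tagged multigraph-free scaffold graph for oracle tests."""
    n = rng.randint(4, max_vertices)
    lengths = {f"c{i:02d}": rng.randint(100, 2000) for i in range(n)}
    graph = ScaffoldGraph(lengths)
    ids = sorted(lengths)
    m = rng.randint(0, max_edges)
    for _ in range(m):
        a, b = rng.sample(ids, 2)
        ea = ContigEnd(a, rng.choice((End.FIVE, End.THREE)))
        eb = ContigEnd(b, rng.choice((End.FIVE, End.THREE)))
        for _ in range(rng.randint(1, 4)):  # weight
            graph.add_gap_sample(ea, eb, rng.uniform(-100, 400))
    if rng.random() < 0.5:
        graph.min_support = 2
    if rng.random() < 0.3:
        graph.repeat_flags = set(rng.sample(ids, rng.randint(1, max(1, n // 5))))
    return graph


# ---------------------------------------------------------------------------
# Smith-Waterman-Gotoh: plain-Python reference


def sw_gotoh_oracle(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> tuple[int, int, int]:
    """(score, identical columns, alignment columns) of the best local
    alignment under the documented conventions: gap of length k costs
    open + (k-1)*extend; state preference diagonal > vertical > horizontal;
    gap states prefer opening on ties; best cell is the first maximum in
    row-major order."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    pH = [[0] * (m + 1) for _ in range(n + 1)]  # 0 stop, 1 diag, 2 from F, 3 from E
    pE = [[0] * (m + 1) for _ in range(n + 1)]  # 1 = opened
    pF = [[0] * (m + 1) for _ in range(n + 1)]

    best = bi = bj = 0
    au, bu = a.upper(), b.upper()
    for i in range(1, n + 1):
        ai = au[i - 1]
        for j in range(1, m + 1):
            e_open, e_ext = H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend
            if e_open >= e_ext:
                E[i][j], pE[i][j] = e_open, 1
            else:
                E[i][j], pE[i][j] = e_ext, 0
            f_open, f_ext = H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend
            if f_open >= f_ext:
                F[i][j], pF[i][j] = f_open, 1
            else:
                F[i][j], pF[i][j] = f_ext, 0
            bj_char = bu[j - 1]
            s = match if (ai == bj_char and ai in "ACGT") else mismatch
            diag = H[i - 1][j - 1] + s
            hb, hp = 0, 0
            if diag >= hb and diag > 0:
                hb, hp = diag, 1
            if F[i][j] > hb:
                hb, hp = F[i][j], 2
            if E[i][j] > hb:
                hb, hp = E[i][j], 3
            H[i][j], pH[i][j] = hb, hp
            if hb > best:
                best, bi, bj = hb, i, j

    matches = columns = 0
    i, j, state = bi, bj, 0
    while True:
        if state == 0:
            p = pH[i][j]
            if p == 0 or H[i][j] == 0:
                break
            if p == 1:
                columns += 1
                if au[i - 1] == bu[j - 1] and au[i - 1] in "ACGT":
                    matches += 1
                i, j = i - 1, j - 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 1:
            columns += 1
            opened = pE[i][j] == 1
            j -= 1
            state = 0 if opened else 1
        else:
            columns += 1
            opened = pF[i][j] == 1
            i -= 1
            state = 0 if opened else 2
    return best, matches, columns


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def mutate(rng: random.Random, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate * 0.8:
            out.append(rng.choice([c for c in "ACGT" if c != ch]))
        elif r < rate * 0.9:
            continue  # deletion
        elif r < rate:
            out.append(ch)
            out.append(rng.choice("ACGT"))  # insertion
        else:
            out.append(ch)
    return "".join(out) or "A"
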