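"""Local (Smith-Waterman) alignment with affine gaps, BLASTn-like scoring.

Default scores: match +2, mismatch -3, gap open -5, gap extend -2, where a
gap of length k costs open + (k-1)*extend (the first gapped base pays the
open penalty). The DP is the three-state Gotoh recursion; tie-breaks are
fixed so that results are fully deterministic:

* cell state preference when scores tie: diagonal > vertical gap (consuming
  sequence A) > horizontal gap (consuming sequence B) > stop;
* within a gap state, opening from the main matrix is preferred over
  extending when scores tie;
* the traceback starts from the best-scoring cell; among equal-scoring
  cells the smallest (row, column) in row-major order wins.

Returns the alignment score, the number of identical columns, and the total
column count (matches + mismatches + gap columns) of that one alignment.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2

# pointer codes for the H (main) matrix
_STOP, _DIAG, _FROM_F, _FROM_E = 0, 1, 2, 3

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A,C,G,T -> 0..3; others 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _sw_gotoh(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    neg = -(10**9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), neg, dtype=np.int64)
    F = np.full((n + 1, m + 1), neg, dtype=np.int64)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = opened from H
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)

    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # E: gap in A (horizontal, consumes b[j-1])
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            # F: gap in B (vertical, consumes a[i-1])
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            # H: best of stop / diagonal / F / E, preference in that tie order
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
            diag = H[i - 1, j - 1] + s
            hbest = 0
            hptr = _STOP
            if diag >= hbest and diag > 0:
                hbest = diag
                hptr = _DIAG
            if F[i, j] > hbest:
                hbest = F[i, j]
                hptr = _FROM_F
            if E[i, j] > hbest:
                hbest = E[i, j]
                hptr = _FROM_E
            H[i, j] = hbest
            ptrH[i, j] = hptr
            if hbest > best:
                best, bi, bj = hbest, i, j

    # traceback from (bi, bj) in state H
    matches = 0
    columns = 0
    i, j = bi, bj
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == _STOP or H[i, j] == 0:
                break
            if p == _DIAG:
                columns += 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == _FROM_F:
                state = 2
            else:
                state = 1
        elif state == 1:  # E: horizontal gap
            columns += 1
            opened = ptrE[i, j] == 1
            j -= 1
            state = 0 if opened else 1
        else:  # F: vertical gap
            columns += 1
            opened = ptrF[i, j] == 1
            i -= 1
            state = 0 if opened else 2
    return best, matches, columns


def smith_waterman(
    seq_a: str,
    seq_b: str,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> tuple[int, int, int]:
    """Best local alignment of two DNA strings.

    Returns ``(score, identical_columns, alignment_columns)``; an empty
    optimal alignment (all-negative scoring) returns ``(0, 0, 0)``."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    score, matches, columns = _sw_gotoh(
        encode(seq_a), encode(seq_b), match, mismatch, gap_open, gap_extend
    )
    return int(score), int(matches), int(columns)
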