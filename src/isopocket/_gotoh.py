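"""Affine-gap global alignment dynamic programming (Gotoh three-state DP).

The fill runs over a precomputed column-pair score matrix, so the same
kernel serves sequence-sequence alignment (substitution-matrix lookups)
and profile-profile alignment (expected-score matrices). A gap run of
length k costs open + (k-1) * extend.

Tie-breaking is fixed so alignments are deterministic: at every choice the
match state is preferred over a gap in the second sequence ("up"), which is
preferred over a gap in the first ("left").
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30

# state codes
M, UP, LEFT = 0, 1, 2


@njit(cache=True)
def gotoh_fill(score: np.ndarray, gap_open: float, gap_extend: float):
    """Fill the three Gotoh matrices for a global affine-gap alignment.

    score[i, j] is the score of aligning position i of A to position j of B.
    Returns (best_score, end_state, ptr) where ptr[s, i, j] is the
    predecessor state of state s at DP cell (i, j).
    """
    n, m = score.shape
    mm = np.full((n + 1, m + 1), NEG_INF)
    fu = np.full((n + 1, m + 1), NEG_INF)  # gap in B, consumes A ("up")
    el = np.full((n + 1, m + 1), NEG_INF)  # gap in A, consumes B ("left")
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)

    mm[0, 0] = 0.0
    for i in range(1, n + 1):
        fu[i, 0] = -(gap_open + (i - 1) * gap_extend)
        ptr[UP, i, 0] = M if i == 1 else UP
    for j in range(1, m + 1):
        el[0, j] = -(gap_open + (j - 1) * gap_extend)
        ptr[LEFT, 0, j] = M if j == 1 else LEFT

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # match state: best predecessor at (i-1, j-1), prefer M > UP > LEFT
            best = mm[i - 1, j - 1]
            arg = M
            if fu[i - 1, j - 1] > best:
                best = fu[i - 1, j - 1]
                arg = UP
            if el[i - 1, j - 1] > best:
                best = el[i - 1, j - 1]
                arg = LEFT
            mm[i, j] = best + score[i - 1, j - 1]
            ptr[M, i, j] = arg

            # gap in B (consume a[i-1]): open from M or LEFT, extend from UP
            best = mm[i - 1, j] - gap_open
            arg = M
            if fu[i - 1, j] - gap_extend > best:
                best = fu[i - 1, j] - gap_extend
                arg = UP
            if el[i - 1, j] - gap_open > best:
                best = el[i - 1, j] - gap_open
                arg = LEFT
            fu[i, j] = best
            ptr[UP, i, j] = arg

            # gap in A (consume b[j-1])
            best = mm[i, j - 1] - gap_open
            arg = M
            if fu[i, j - 1] - gap_open > best:
                best = fu[i, j - 1] - gap_open
                arg = UP
            if el[i, j - 1] - gap_extend > best:
                best = el[i, j - 1] - gap_extend
                arg = LEFT
            el[i, j] = best
            ptr[LEFT, i, j] = arg

    best = mm[n, m]
    end_state = M
    if fu[n, m] > best:
        best = fu[n, m]
        end_state = UP
    if el[n, m] > best:
        best = el[n, m]
        end_state = LEFT
    return best, end_state, ptr


def traceback(end_state: int, ptr: np.ndarray, n: int, m: int) -> list[int]:
    """Recover the move list (M/UP/LEFT codes, start to end) from the fill."""
    moves: list[int] = []
    i, j, s = n, m, end_state
    while i > 0 or j > 0:
        moves.append(s)
        prev = int(ptr[s, i, j])
        if s == M:
            i, j = i - 1, j - 1
        elif s == UP:
            i -= 1
        else:
            j -= 1
        s = prev
    moves.reverse()
    return moves
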