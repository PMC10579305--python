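"""Numba kernels for affine-gap dynamic programming.

The Smith-Waterman fill uses the standard three-state recurrence (match state
M, gap-in-subject state X consuming the query, gap-in-query state Y consuming
the subject).  Opening a gap of length 1 costs ``gap_open + gap_extend`` and
each further gapped residue costs ``gap_extend``, matching the BLAST
convention in which a length-k gap costs ``open + k * extend``.

Determinism: ties in each recurrence are broken in the fixed order
M > X > Y > restart, and the maximal cell is the first encountered in
row-major order, i.e. the one with the lexicographically smallest
(query end, subject end).

``band`` > 0 excludes all cells with ``|i - j| < band`` from the table; this
is used for off-diagonal self-alignment when searching for internal repeats.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10**8))

# traceback codes for the M state
TB_STOP = 0  # local alignment starts here
TB_M = 1  # diagonal, from M
TB_X = 2  # diagonal, from X
TB_Y = 3  # diagonal, from Y
# traceback codes for the X / Y states
TB_OPEN = 1
TB_EXTEND = 2


@njit(cache=True)
def sw_fill(a, b, S, gap_open, gap_extend, band):  # pragma: no cover - jit
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    go = np.int32(gap_open + gap_extend)
    ge = np.int32(gap_extend)
    best = np.int32(0)
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if band > 0 and abs(i - j) < band:
                continue
            s = S[a[i - 1], b[j - 1]]
            # M: tie order M > X > Y > restart
            prev = M[i - 1, j - 1]
            p = TB_M
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
                p = TB_X
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
                p = TB_Y
            if 0 > prev:
                prev = np.int32(0)
                p = TB_STOP
            M[i, j] = prev + s
            ptr_m[i, j] = p
            # X: gap in b, consumes a ("up"); tie prefers opening from M
            o = M[i - 1, j] - go
            e = X[i - 1, j] - ge
            if o >= e:
                X[i, j] = o
                ptr_x[i, j] = TB_OPEN
            else:
                X[i, j] = e
                ptr_x[i, j] = TB_EXTEND
            # Y: gap in a, consumes b ("left")
            o = M[i, j - 1] - go
            e = Y[i, j - 1] - ge
            if o >= e:
                Y[i, j] = o
                ptr_y[i, j] = TB_OPEN
            else:
                Y[i, j] = e
                ptr_y[i, j] = TB_EXTEND
            if M[i, j] > best:
                best = M[i, j]
                best_i = i
                best_j = j
    return best, best_i, best_j, ptr_m, ptr_x, ptr_y


@njit(cache=True)
def sw_score_only(a, b, S, gap_open, gap_extend, band):  # pragma: no cover - jit
    """Best local-alignment score only (rolling rows, no traceback)."""
    n = a.shape[0]
    m = b.shape[0]
    M_prev = np.full(m + 1, NEG, dtype=np.int32)
    X_prev = np.full(m + 1, NEG, dtype=np.int32)
    Y_prev = np.full(m + 1, NEG, dtype=np.int32)
    M_cur = np.full(m + 1, NEG, dtype=np.int32)
    X_cur = np.full(m + 1, NEG, dtype=np.int32)
    Y_cur = np.full(m + 1, NEG, dtype=np.int32)
    go = np.int32(gap_open + gap_extend)
    ge = np.int32(gap_extend)
    best = np.int32(0)
    for i in range(1, n + 1):
        M_cur[0] = NEG
        X_cur[0] = NEG
        Y_cur[0] = NEG
        for j in range(1, m + 1):
            if band > 0 and abs(i - j) < band:
                M_cur[j] = NEG
                X_cur[j] = NEG
                Y_cur[j] = NEG
                continue
            prev = M_prev[j - 1]
            if X_prev[j - 1] > prev:
                prev = X_prev[j - 1]
            if Y_prev[j - 1] > prev:
                prev = Y_prev[j - 1]
            if 0 > prev:
                prev = np.int32(0)
            M_cur[j] = prev + S[a[i - 1], b[j - 1]]
            o = M_prev[j] - go
            e = X_prev[j] - ge
            X_cur[j] = o if o >= e else e
            o = M_cur[j - 1] - go
            e = Y_cur[j - 1] - ge
            Y_cur[j] = o if o >= e else e
            if M_cur[j] > best:
                best = M_cur[j]
        M_prev, M_cur = M_cur, M_prev
        X_prev, X_cur = X_cur, X_prev
        Y_prev, Y_cur = Y_cur, Y_prev
    return best


def sw_traceback(
    best_i: int, best_j: int, ptr_m, ptr_x, ptr_y
) -> list[tuple[int, int]]:
    """Recover aligned columns ending at (best_i, best_j).

    Returns a list of (query_index, subject_index) pairs in alignment order;
    -1 marks a gap in the respective sequence.  Local alignments always start
    and end in the M state.
    """
    cols: list[tuple[int, int]] = []
    i, j = best_i, best_j
    state = "M"
    while True:
        if state == "M":
            p = ptr_m[i, j]
            cols.append((i - 1, j - 1))
            i -= 1
            j -= 1
            if p == TB_STOP:
                break
            state = "M" if p == TB_M else ("X" if p == TB_X else "Y")
        elif state == "X":
            p = ptr_x[i, j]
            cols.append((i - 1, -1))
            i -= 1
            state = "M" if p == TB_OPEN else "X"
        else:
            p = ptr_y[i, j]
            cols.append((-1, j - 1))
            j -= 1
            state = "M" if p == TB_OPEN else "Y"
    cols.reverse()
    return cols
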