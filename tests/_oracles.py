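"""Independent reference implementations used only by the tests.

These are deliberately written as plain, slow Python over the full dynamic
programming tables / the full subset lattice, so they share no code with the
package's optimized implementations.
"""

from __future__ import annotations

from itertools import combinations

from Bio.Align import substitution_matrices

_MATRIX_CACHE: dict[str, dict[tuple[str, str], int]] = {}


def _scores(matrix_name: str) -> dict[tuple[str, str], int]:
    if matrix_name not in _MATRIX_CACHE:
        mat = substitution_matrices.load(matrix_name)
        _MATRIX_CACHE[matrix_name] = {
            (x, y): int(mat[x, y]) for x in mat.alphabet for y in mat.alphabet
        }
    return _MATRIX_CACHE[matrix_name]


def oracle_local_align(
    a: str,
    b: str,
    gap_open: int = 11,
    gap_extend: int = 1,
    matrix_name: str = "BLOSUM62",
    band: int = 0,
):
    """Brute-force affine-gap local alignment over the full three-matrix DP
    table, with the documented tie-break (diagonal over up over left;
    smallest (q_end, s_end) among maximal cells; a length-1 gap costs
    gap_open + gap_extend).

    Returns None if no positive-scoring cell, else a dict with score,
    identities, positives and aln_len.  ``band`` > 0 excludes cells within
    ``band`` of the main diagonal.
    """
    S = _scores(matrix_name)
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    go, ge = gap_open + gap_extend, gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if band > 0 and abs(i - j) < band:
                continue
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0) + S[
                (a[i - 1], b[j - 1])
            ]
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - ge)
    best, bi, bj = 0, None, None
    for i in range(n + 1):
        for j in range(m + 1):
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j
    if bi is None:
        return None
    identities = positives = aln_len = 0
    i, j, state = bi, bj, "M"
    while True:
        if state == "M":
            aln_len += 1
            s = S[(a[i - 1], b[j - 1])]
            if a[i - 1] == b[j - 1]:
                identities += 1
            if s > 0:
                positives += 1
            sources = [M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0]
            top = max(sources)
            choice = sources.index(top)  # first of M, X, Y, restart
            i, j = i - 1, j - 1
            if choice == 3:
                break
            state = "MXY"[choice]
        elif state == "X":
            aln_len += 1
            state = "M" if M[i - 1][j] - go >= X[i - 1][j] - ge else "X"
            i -= 1
        else:
            aln_len += 1
            state = "M" if M[i][j - 1] - go >= Y[i][j - 1] - ge else "Y"
            j -= 1
    return {
        "score": int(best),
        "identities": identities,
        "positives": positives,
        "aln_len": aln_len,
        "q_end": bi,
        "s_end": bj,
    }


def _chain_valid(sel, max_gap: int) -> bool:
    """Validity of a rank_a-sorted pair subset under the block rule."""
    ranks_b = [p.rank_b for p in sel]
    for p, q in zip(sel, sel[1:]):
        if q.rank_a - p.rank_a - 1 > max_gap:
            return False
    inc = all(y > x for x, y in zip(ranks_b, ranks_b[1:]))
    dec = all(y < x for x, y in zip(ranks_b, ranks_b[1:]))
    return inc or dec


def oracle_blocks(pairs, min_genes: int = 5, max_gap: int = 4):
    """Exhaustive block finder: all pair subsets satisfying the rule, kept
    only if maximal, then resolved greedily left-to-right (longer chain wins
    at equal start).  Returns blocks as lists of (rank_a, rank_b)."""
    pairs = sorted(pairs, key=lambda p: p.rank_a)
    idx = range(len(pairs))
    valid = []
    for r in range(1, len(pairs) + 1):
        for comb in combinations(idx, r):
            sel = [pairs[i] for i in comb]
            if _chain_valid(sel, max_gap):
                valid.append(frozenset(comb))
    maximal = [s for s in valid if not any(s < t for t in valid)]
    chains = [[pairs[i] for i in sorted(s)] for s in maximal]
    chains = [c for c in chains if len(c) >= min_genes]
    chains.sort(
        key=lambda c: (
            c[0].rank_a,
            -len(c),
            tuple(p.rank_a for p in c),
            tuple(p.rank_b for p in c),
        )
    )
    out, used = [], set()
    for c in chains:
        keys = {(p.rank_a, p.rank_b) for p in c}
        if keys & used:
            continue
        used |= keys
        out.append([(p.rank_a, p.rank_b) for p in c])
    out.sort(key=lambda c: c[0][0])
    return out
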