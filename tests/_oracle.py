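"""Brute-force oracles used by the test suite.

Pure-Python affine-gap DP plus backward enumeration over optimal-path
edges.  Deliberately independent of pegquant.align (no numpy kernels, no
constrained forward pass): the implementation answers "does an optimal
alignment without window indels exist" with a second constrained DP,
whereas this oracle walks the optimal-path graph backwards.
"""

from __future__ import annotations

import sys

MATCH, MISMATCH, OPEN, EXT = 5.0, -4.0, -20.0, -2.0
NEG = float("-inf")


def dp_tables(ref: str, read: str):
    """Three-state global affine DP (gap run of length L costs OPEN+(L-1)*EXT)."""
    n, m = len(ref), len(read)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read (deletion)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (insertion)
    M[0][0] = 0.0
    for j in range(1, m + 1):
        Y[0][j] = OPEN + (j - 1) * EXT
    for i in range(1, n + 1):
        X[i][0] = OPEN + (i - 1) * EXT
    for i in range(1, n + 1):
        a = ref[i - 1]
        for j in range(1, m + 1):
            s = MATCH if (a == read[j - 1] and a != "N") else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + OPEN, X[i - 1][j] + EXT)
            Y[i][j] = max(M[i][j - 1] + OPEN, Y[i][j - 1] + EXT)
    return M, X, Y


def opt_score(ref: str, read: str) -> float:
    M, X, Y = dp_tables(ref, read)
    return max(M[-1][-1], X[-1][-1], Y[-1][-1])


def exists_clean_optimal(ref: str, read: str, span: tuple[int, int]) -> bool:
    """True iff some optimal-score alignment has no indel column inside span.

    A deletion column consuming reference position p is "in window" when
    span[0] <= p < span[1]; an insertion column counts via its left anchor
    (the reference index 5' of the gap).
    """
    lo, hi = span
    M, X, Y = dp_tables(ref, read)
    n, m = len(ref), len(read)
    best = max(M[n][m], X[n][m], Y[n][m])
    sys.setrecursionlimit(20000)
    memo: dict[tuple[int, int, int], bool] = {}

    def walk(i: int, j: int, state: int) -> bool:
        # state 0=M, 1=X(deletion), 2=Y(insertion); True if (0,0) reachable
        # backwards along optimal edges without an in-window indel column.
        if i == 0 and j == 0:
            return state == 0
        key = (i, j, state)
        if key in memo:
            return memo[key]
        ok = False
        if state == 0 and i > 0 and j > 0:
            a = ref[i - 1]
            s = MATCH if (a == read[j - 1] and a != "N") else MISMATCH
            target = M[i][j] - s
            for ps, tab in ((0, M), (1, X), (2, Y)):
                if tab[i - 1][j - 1] == target and walk(i - 1, j - 1, ps):
                    ok = True
                    break
        elif state == 1 and i > 0:
            if not (lo <= i - 1 < hi):  # this deletion column consumes ref i-1
                cur = X[i][j]
                if M[i - 1][j] + OPEN == cur and walk(i - 1, j, 0):
                    ok = True
                elif X[i - 1][j] + EXT == cur and walk(i - 1, j, 1):
                    ok = True
        elif state == 2 and j > 0:
            if not (lo <= i - 1 < hi):  # insertion left anchor is ref i-1
                cur = Y[i][j]
                if M[i][j - 1] + OPEN == cur and walk(i, j - 1, 0):
                    ok = True
                elif Y[i][j - 1] + EXT == cur and walk(i, j - 1, 2):
                    ok = True
        memo[key] = ok
        return ok

    return any(tab[n][m] == best and walk(n, m, st)
               for st, tab in ((0, M), (1, X), (2, Y)))


def classify_oracle(read: str, ref: str, hdr: str, ref_span: tuple[int, int],
                    hdr_span: tuple[int, int]):
    """Assign and classify a read the way the pipeline defines it.

    Returns 'hdr_clean', 'hdr_indel', 'ref_clean' or 'ref_indel'.
    Assignment is by optimal score with ties to the reference; callers
    generate near-identical reads, so the identity floor never binds.
    """
    s_ref = opt_score(ref, read)
    s_hdr = opt_score(hdr, read)
    if s_hdr > s_ref:
        allele, span, label = hdr, hdr_span, "hdr"
    else:
        allele, span, label = ref, ref_span, "ref"
    clean = exists_clean_optimal(allele, read, span)
    return f"{label}_{'clean' if clean else 'indel'}"
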