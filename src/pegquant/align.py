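"""Global affine-gap alignment of amplicon reads against candidate alleles.

This is a deliberately small re-implementation of the alignment subset the
outcome classifier needs: Needleman–Wunsch with affine gap costs, a
score-only kernel, a kernel with gap transitions *forbidden inside a
reference interval* (used to decide, path-independently, whether a read can
be explained without an indel in the quantification window), and a
traceback that yields per-column reference coordinates.

Scoring defaults follow common amplicon-quantifier practice: match +5,
mismatch -4, gap open -20, gap extend -2, where a gap run of length L costs
``open + (L - 1) * extend``.  N never matches anything.

Kernels are numba-jitted; sequences are encoded as uint8 codes (A=0 C=1 G=2
T=3, anything else = N = 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["AlignParams", "Alignment", "align", "best_score",
           "best_score_no_window_indel", "encode"]

NEG = -1e30

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignParams:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -20.0
    gap_extend: float = -2.0
    identity_floor: float = 0.60
    tie_break: str = "ref"  # assignment on equal REF/HDR scores


@njit(cache=True)
def _affine_score(ref, read, match, mismatch, gap_open, gap_extend,
                  del_lo, del_hi, ins_lo, ins_hi):
    """Best global score; gap transitions are forbidden where
    * a deletion (gap in read) would consume a reference base in [del_lo, del_hi)
    * an insertion (gap in ref) would have its left-anchor reference index in
      [ins_lo, ins_hi).
    Pass empty intervals (lo >= hi) for unconstrained alignment.
    """
    n, m = len(ref), len(read)
    M = np.full(m + 1, NEG)
    X = np.full(m + 1, NEG)   # gap in read (deletion), consumes ref
    Y = np.full(m + 1, NEG)   # gap in ref (insertion), consumes read
    M[0] = 0.0
    # leading insertions (ref anchor -1)
    if not (ins_lo <= -1 < ins_hi):
        for j in range(1, m + 1):
            Y[j] = gap_open + (j - 1) * gap_extend
    Mp = np.empty(m + 1)
    Xp = np.empty(m + 1)
    Yp = np.empty(m + 1)
    for i in range(1, n + 1):
        for j in range(m + 1):
            Mp[j] = M[j]
            Xp[j] = X[j]
            Yp[j] = Y[j]
        rbase = ref[i - 1]
        del_ok = not (del_lo <= i - 1 < del_hi)
        ins_ok = not (ins_lo <= i - 1 < ins_hi)
        for j in range(m + 1):
            # X: deletion consuming ref base i-1
            if del_ok:
                best = Mp[j] + gap_open
                if Xp[j] + gap_extend > best:
                    best = Xp[j] + gap_extend
                X[j] = best
            else:
                X[j] = NEG
            # M: diagonal
            if j > 0:
                s = match if (rbase == read[j - 1] and rbase < 4) else mismatch
                best = Mp[j - 1]
                if Xp[j - 1] > best:
                    best = Xp[j - 1]
                if Yp[j - 1] > best:
                    best = Yp[j - 1]
                M[j] = best + s
            else:
                M[j] = NEG
            # Y: insertion consuming read base j-1, left anchor = i-1
            if j > 0 and ins_ok:
                best = M[j - 1] + gap_open
                if Y[j - 1] + gap_extend > best:
                    best = Y[j - 1] + gap_extend
                Y[j] = best
            elif j > 0:
                Y[j] = NEG
            else:
                Y[j] = NEG
    best = M[m]
    if X[m] > best:
        best = X[m]
    if Y[m] > best:
        best = Y[m]
    return best


@njit(cache=True)
def _affine_traceback(ref, read, match, mismatch, gap_open, gap_extend):
    """Full DP with traceback.

    Returns (score, ops) where ops is an int8 array over alignment columns
    in order: 0 = diagonal (match/mismatch), 1 = deletion column (gap in
    read), 2 = insertion column (gap in ref).  Tie preference at each step:
    diagonal, then deletion, then insertion.
    """
    n, m = len(ref), len(read)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for i in range(1, n + 1):
        rbase = ref[i - 1]
        for j in range(1, m + 1):
            s = match if (rbase == read[j - 1] and rbase < 4) else mismatch
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + s
            b = M[i - 1, j] + gap_open
            if X[i - 1, j] + gap_extend > b:
                b = X[i - 1, j] + gap_extend
            X[i, j] = b
            b = M[i, j - 1] + gap_open
            if Y[i, j - 1] + gap_extend > b:
                b = Y[i, j - 1] + gap_extend
            Y[i, j] = b
    # final state: prefer M, then X, then Y
    i, j = n, m
    score = M[i, j]
    state = 0
    if X[i, j] > score:
        score, state = X[i, j], 1
    if Y[i, j] > score:
        score, state = Y[i, j], 2
    ops = np.empty(n + m, dtype=np.int8)
    k = n + m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            ops[k] = 0
            # which predecessor fed M[i,j]?
            prev = M[i, j] - (match if (ref[i - 1] == read[j - 1] and ref[i - 1] < 4)
                              else mismatch)
            i -= 1
            j -= 1
            if abs(M[i, j] - prev) < 1e-9:
                state = 0
            elif abs(X[i, j] - prev) < 1e-9:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 1
            cur = X[i, j]
            i -= 1
            if abs(M[i, j] + gap_open - cur) < 1e-9:
                state = 0
            else:
                state = 1
        else:
            ops[k] = 2
            cur = Y[i, j]
            j -= 1
            if abs(M[i, j] + gap_open - cur) < 1e-9:
                state = 0
            else:
                state = 2
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return score, ops[k:]


@dataclass
class Alignment:
    """A global alignment of a read to a reference allele.

    ``ops`` is one code per alignment column: 0 diagonal, 1 deletion (gap in
    read at a reference position), 2 insertion (extra read base; its left
    anchor is the reference index immediately 5' of the gap).
    """

    score: float
    ops: np.ndarray
    ref_seq: str
    read_seq: str

    @property
    def n_columns(self) -> int:
        return len(self.ops)

    def matches(self) -> int:
        n = 0
        i = j = 0
        for op in self.ops:
            if op == 0:
                a, b = self.ref_seq[i], self.read_seq[j]
                if a == b and a != "N":
                    n += 1
                i += 1
                j += 1
            elif op == 1:
                i += 1
            else:
                j += 1
        return n

    @property
    def identity(self) -> float:
        return self.matches() / max(1, self.n_columns)

    def indel_segments(self):
        """Yield ('del', ref_start, ref_end) / ('ins', left_anchor, length)."""
        i = j = 0
        k = 0
        ops = self.ops
        while k < len(ops):
            op = ops[k]
            if op == 0:
                i += 1
                j += 1
                k += 1
            elif op == 1:
                start = i
                while k < len(ops) and ops[k] == 1:
                    i += 1
                    k += 1
                yield ("del", start, i)
            else:
                anchor = i - 1
                length = 0
                while k < len(ops) and ops[k] == 2:
                    j += 1
                    k += 1
                    length += 1
                yield ("ins", anchor, length)

    def read_base_at(self, ref_pos: int) -> str | None:
        """Read base aligned to reference position ``ref_pos`` (None if gapped)."""
        i = j = 0
        for op in self.ops:
            if op == 0:
                if i == ref_pos:
                    return self.read_seq[j]
                i += 1
                j += 1
            elif op == 1:
                if i == ref_pos:
                    return None
                i += 1
            else:
                j += 1
        return None


def align(ref_seq: str, read_seq: str, params: AlignParams = AlignParams()) -> Alignment:
    """Canonical global affine-gap alignment with traceback."""
    score, ops = _affine_traceback(encode(ref_seq), encode(read_seq),
                                   params.match, params.mismatch,
                                   params.gap_open, params.gap_extend)
    return Alignment(float(score), ops, ref_seq, read_seq)


def best_score(ref_seq: str, read_seq: str, params: AlignParams = AlignParams()) -> float:
    return float(_affine_score(encode(ref_seq), encode(read_seq),
                               params.match, params.mismatch,
                               params.gap_open, params.gap_extend,
                               0, 0, 0, 0))


def best_score_no_window_indel(ref_seq: str, read_seq: str, span: tuple[int, int],
                               params: AlignParams = AlignParams()) -> float:
    """Best global score among alignments with no indel in the window.

    Deletions consuming a reference base in ``[span[0], span[1])`` and
    insertions whose left anchor lies in that half-open interval are
    forbidden.  Comparing this with :func:`best_score` decides whether the
    read *requires* a window indel under optimal alignment.
    """
    lo, hi = span
    return float(_affine_score(encode(ref_seq), encode(read_seq),
                               params.match, params.mismatch,
                               params.gap_open, params.gap_extend,
                               lo, hi, lo, hi))
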