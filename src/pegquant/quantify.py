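"""Read-level classification of prime-editing outcomes.

Each amplicon read that passes the mean-quality filter is globally aligned
to two candidate alleles — the unedited reference and the expected
intended-edit (HDR) allele — and assigned to the higher-scoring one.  A
read is "indel-containing" when no optimal-score alignment to its assigned
allele avoids insertions/deletions inside the quantification window centred
at the pegRNA nick.  The five headline outcome frequencies are proportions
of reads that aligned to either allele:

* intended edit without indels  = HDR-assigned, indel-free / n_aligned
* intended edit with indels     = HDR-assigned, window indel / n_aligned
* total intended edit           = sum of the two above
* total indels                  = all window-indel reads / n_aligned
* indels without intended edit  = REF-assigned, window indel / n_aligned

Headline reporting convention: "intended edit" means the without-indel
frequency; "indels" means total indels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .align import AlignParams, Alignment, align, best_score, best_score_no_window_indel
from .design import (AmpliconReference, PegRNADesign, QuantWindow,
                     build_edited_allele, edit_windows, locate_protospacer,
                     nick_position)

__all__ = ["EmptyRead", "OutcomeTally", "QuantifyResult", "ReadClass",
           "ReadRecord", "ZeroAligned", "align_and_assign", "classify_read",
           "passes_quality", "quantify_reads", "tally"]


class EmptyRead(ValueError):
    """Zero-length read."""


class ZeroAligned(ZeroDivisionError):
    """No read aligned to any amplicon; frequencies are undefined."""


class ReadClass(Enum):
    HDR_CLEAN = "hdr_clean"
    HDR_INDEL = "hdr_indel"
    REF_INDEL = "ref_indel"
    REF_CLEAN = "ref_clean"
    DISCARDED_QUALITY = "discarded_quality"
    UNALIGNED = "unaligned"


ALIGNED_CLASSES = (ReadClass.HDR_CLEAN, ReadClass.HDR_INDEL,
                   ReadClass.REF_INDEL, ReadClass.REF_CLEAN)


@dataclass(frozen=True)
class ReadRecord:
    id: str
    seq: str
    quals: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.quals is not None:
            if len(self.quals) != len(self.seq):
                raise ValueError("quals length must equal sequence length")
            if any(q < 0 for q in self.quals):
                raise ValueError("Phred scores must be >= 0")

    def mean_quality(self) -> float:
        if not self.seq:
            raise EmptyRead(self.id)
        if self.quals is None:
            return float("inf")
        return float(np.mean(self.quals))


def passes_quality(read: ReadRecord, min_mean_q: float = 30.0) -> bool:
    """True iff the read's mean Phred quality is >= ``min_mean_q``."""
    return read.mean_quality() >= min_mean_q


@dataclass
class ReadAssignment:
    """Outcome of aligning one read against both candidate alleles."""

    assigned: str | None          # 'REF', 'HDR' or None
    score: float
    identity: float
    allele_seq: str | None
    read_seq: str
    window: QuantWindow | None
    # substitution-only fast path: the read aligns gaplessly end-to-end
    gapless: bool = False
    _alignment: Alignment | None = field(default=None, repr=False)

    @property
    def alignment(self) -> Alignment | None:
        """Canonical traceback alignment (computed lazily; None if unaligned)."""
        if self._alignment is None and self.assigned is not None and not self.gapless:
            self._alignment = align(self.allele_seq, self.read_seq)
        if self.gapless and self._alignment is None:
            ops = np.zeros(len(self.read_seq), dtype=np.int8)
            self._alignment = Alignment(self.score, ops, self.allele_seq, self.read_seq)
        return self._alignment


def _hamming(a: str, b: str) -> int:
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    n_mask = (x == ord("N")) | (y == ord("N"))
    return int(np.count_nonzero((x != y) | n_mask))


# With match +5 / mismatch -4 / open -20, a gapped alignment of equal-length
# sequences scores at most 5*len - 45, so the gapless alignment is provably
# optimal whenever it has <= 4 mismatches (9*4 < 45).
_GAPLESS_SAFE_MISMATCHES = 4


def _score_one(allele: str, read: str, params: AlignParams):
    """(score, identity, gapless) for one allele, with substitution fast path."""
    if len(allele) == len(read):
        h = _hamming(allele, read)
        if h <= _GAPLESS_SAFE_MISMATCHES:
            score = params.match * (len(read) - h) + params.mismatch * h
            return score, (len(read) - h) / len(read), True
    s = best_score(allele, read, params)
    return s, None, False


def align_and_assign(read: ReadRecord | str, ref_seq: str, hdr_seq: str,
                     ref_window: QuantWindow | None = None,
                     hdr_window: QuantWindow | None = None,
                     params: AlignParams = AlignParams()) -> ReadAssignment:
    """Align a read to both alleles and assign it to the higher-scoring one.

    Ties go to the reference by default (never inflating the intended-edit
    frequency); set ``params.tie_break = 'hdr'`` to invert.  Reads whose best
    alignment identity falls below ``params.identity_floor`` are unassigned.
    """
    seq = read.seq if isinstance(read, ReadRecord) else read
    if not seq:
        raise EmptyRead(getattr(read, "id", "<read>"))
    ref_score, ref_ident, ref_gapless = _score_one(ref_seq, seq, params)
    hdr_score, hdr_ident, hdr_gapless = _score_one(hdr_seq, seq, params)

    if hdr_score > ref_score or (hdr_score == ref_score and params.tie_break == "hdr"):
        assigned, score, ident, gapless = "HDR", hdr_score, hdr_ident, hdr_gapless
        allele, window = hdr_seq, hdr_window
    else:
        assigned, score, ident, gapless = "REF", ref_score, ref_ident, ref_gapless
        allele, window = ref_seq, ref_window

    asn = ReadAssignment(assigned, score, 0.0, allele, seq, window, gapless)
    if ident is None:
        ident = asn.alignment.identity
    asn.identity = ident
    if ident < params.identity_floor:
        return ReadAssignment(None, score, ident, None, seq, None)
    return asn


def classify_read(assignment: ReadAssignment, window: QuantWindow | None = None,
                  params: AlignParams = AlignParams()) -> ReadClass:
    """Map an assigned read to its outcome class.

    A read is indel-containing iff every optimal alignment to its assigned
    allele places an insertion or deletion inside the window (half-open
    span; an insertion counts when its left anchor lies in the span).
    Substitution-only discrepancies never count as indels.
    """
    if assignment.assigned is None:
        return ReadClass.UNALIGNED
    win = window or assignment.window
    if win is None:
        raise ValueError("a quantification window is required")
    if assignment.gapless:
        has_window_indel = False
    else:
        aln = assignment.alignment
        canonical_hit = False
        for kind, a, b in aln.indel_segments():
            if kind == "del" and win.overlaps(a, b):
                canonical_hit = True
                break
            if kind == "ins" and win.contains(a):
                canonical_hit = True
                break
        if not canonical_hit:
            has_window_indel = False
        else:
            constrained = best_score_no_window_indel(
                assignment.allele_seq, assignment.read_seq, win.span, params)
            has_window_indel = constrained < assignment.score - 1e-6
    if assignment.assigned == "HDR":
        return ReadClass.HDR_INDEL if has_window_indel else ReadClass.HDR_CLEAN
    return ReadClass.REF_INDEL if has_window_indel else ReadClass.REF_CLEAN


@dataclass(frozen=True)
class OutcomeTally:
    """Per-class read counts and the five outcome frequencies.

    Frequencies are exact rationals internally (``exact_frequencies``), so
    the partition identities — total intended = without + with indels,
    total indels = with intended + without — hold exactly; the float
    properties are the correctly rounded values of those rationals.
    """

    counts: dict

    @classmethod
    def from_classes(cls, classes: Iterable[ReadClass]) -> "OutcomeTally":
        c = Counter(classes)
        return cls({rc: c.get(rc, 0) for rc in ReadClass})

    @property
    def n_aligned(self) -> int:
        return sum(self.counts[rc] for rc in ALIGNED_CLASSES)

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def _frac(self, *rcs: ReadClass) -> Fraction:
        n = self.n_aligned
        if n == 0:
            raise ZeroAligned("no read aligned to any amplicon")
        return Fraction(sum(self.counts[rc] for rc in rcs), n)

    def exact_frequencies(self) -> dict:
        """The five frequencies as exact :class:`~fractions.Fraction` values."""
        return {
            "f_intended_wo_indel": self._frac(ReadClass.HDR_CLEAN),
            "f_intended_w_indel": self._frac(ReadClass.HDR_INDEL),
            "f_total_intended": self._frac(ReadClass.HDR_CLEAN, ReadClass.HDR_INDEL),
            "f_total_indels": self._frac(ReadClass.HDR_INDEL, ReadClass.REF_INDEL),
            "f_indels_wo_intended": self._frac(ReadClass.REF_INDEL),
        }

    @property
    def f_intended_wo_indel(self) -> float:
        return float(self._frac(ReadClass.HDR_CLEAN))

    @property
    def f_intended_w_indel(self) -> float:
        return float(self._frac(ReadClass.HDR_INDEL))

    @property
    def f_indels_wo_intended(self) -> float:
        return float(self._frac(ReadClass.REF_INDEL))

    @property
    def f_total_intended(self) -> float:
        return float(self._frac(ReadClass.HDR_CLEAN, ReadClass.HDR_INDEL))

    @property
    def f_total_indels(self) -> float:
        return float(self._frac(ReadClass.HDR_INDEL, ReadClass.REF_INDEL))

    def as_dict(self) -> dict:
        d = {rc.value: self.counts[rc] for rc in ReadClass}
        d.update(n_aligned=self.n_aligned,
                 f_intended_wo_indel=self.f_intended_wo_indel,
                 f_intended_w_indel=self.f_intended_w_indel,
                 f_total_intended=self.f_total_intended,
                 f_total_indels=self.f_total_indels,
                 f_indels_wo_intended=self.f_indels_wo_intended)
        return d


def tally(classes: Sequence[ReadClass]) -> OutcomeTally:
    """Aggregate per-read classes into an :class:`OutcomeTally`."""
    return OutcomeTally.from_classes(classes)


@dataclass
class QuantifyResult:
    tally: OutcomeTally
    classes: list[ReadClass]
    ref_window: QuantWindow
    hdr_window: QuantWindow
    hdr_seq: str
    cut: int
    strand: str


def quantify_reads(reads: Iterable[ReadRecord], amplicon: AmpliconReference,
                   design: PegRNADesign, min_mean_q: float = 30.0,
                   half_width: int = 10,
                   params: AlignParams = AlignParams()) -> QuantifyResult:
    """Full pipeline: locate the nick, build the edited allele, classify reads."""
    hit = locate_protospacer(amplicon, design)
    cut = nick_position(hit)
    hdr_seq = build_edited_allele(amplicon, cut, hit.strand, design.intended_edit)
    ref_win, hdr_win = edit_windows(amplicon, cut, hit.strand,
                                    design.intended_edit, half_width)
    classes: list[ReadClass] = []
    for read in reads:
        if not passes_quality(read, min_mean_q):
            classes.append(ReadClass.DISCARDED_QUALITY)
            continue
        asn = align_and_assign(read, amplicon.sequence, hdr_seq,
                               ref_win, hdr_win, params)
        classes.append(classify_read(asn, params=params))
    return QuantifyResult(tally(classes), classes, ref_win, hdr_win,
                          hdr_seq, cut, hit.strand)
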