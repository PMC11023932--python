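"""Target-site geometry for prime editing.

A pegRNA directs a Cas9 nickase to a protospacer, nicks the
protospacer-containing strand 3 nt 5' of the PAM, and reverse-transcribes
its 3' extension (RT template) into the released 3' DNA end.  Everything
downstream in this package — outcome classification, the quantification
window, off-target flap walking — is anchored on the nick ("cut")
coordinate defined here.

Conventions
-----------
* Amplicon coordinates are 0-based, half-open, on the + strand.
* The cut coordinate ``c`` means the nicked strand is cleaved between
  + strand positions ``c - 1`` and ``c``.
* Edit positions are 1-based distances 3' of the nick *on the nicked
  strand*: position +1 is the first base 3' of the cut.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "AmbiguousProtospacer",
    "AmpliconReference",
    "EditSpec",
    "OutOfBounds",
    "PegRNADesign",
    "ProtospacerHit",
    "ProtospacerNotFound",
    "QuantWindow",
    "RefMismatch",
    "build_edited_allele",
    "locate_protospacer",
    "nick_position",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

# IUPAC degenerate nucleotide codes, for PAM patterns such as NGG / NNGRRT.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returned as DNA)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _pam_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        try:
            opts = _IUPAC[ch]
        except KeyError:  # pragma: no cover - validated upstream
            raise ValueError(f"invalid IUPAC code {ch!r} in PAM pattern")
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


class ProtospacerNotFound(ValueError):
    """The spacer+PAM was not found on either strand of the amplicon."""


class AmbiguousProtospacer(ValueError):
    """The spacer+PAM occurs more than once on the amplicon."""


class RefMismatch(ValueError):
    """An edit's reference allele disagrees with the amplicon sequence."""


class OutOfBounds(ValueError):
    """An interval falls outside the amplicon."""


@dataclass(frozen=True)
class AmpliconReference:
    """A named amplicon reference sequence (uppercase DNA over A/C/G/T/N)."""

    name: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise ValueError("amplicon sequence is empty")
        if not set(seq) <= set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"amplicon contains non-DNA characters: {bad}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EditSpec:
    """An intended edit, expressed relative to the nick on the nicked strand.

    ``position_rel_nick`` >= 1; +1 is the first base 3' of the nick.  Alleles
    are written 5'->3' on the nicked strand.  A substitution has equal-length
    non-empty ref/alt, an insertion has an empty ref, a deletion an empty alt.
    """

    edit_type: Literal["substitution", "insertion", "deletion"]
    position_rel_nick: int
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self):
        object.__setattr__(self, "ref_allele", self.ref_allele.upper().replace("U", "T"))
        object.__setattr__(self, "alt_allele", self.alt_allele.upper().replace("U", "T"))
        if self.position_rel_nick < 1:
            raise ValueError("edit position must be >= +1 relative to the nick")
        ref, alt = self.ref_allele, self.alt_allele
        if self.edit_type == "substitution":
            if not ref or len(ref) != len(alt):
                raise ValueError("substitution needs equal-length non-empty ref/alt")
        elif self.edit_type == "insertion":
            if ref or not alt:
                raise ValueError("insertion needs empty ref and non-empty alt")
        elif self.edit_type == "deletion":
            if alt or not ref:
                raise ValueError("deletion needs non-empty ref and empty alt")
        else:
            raise ValueError(f"unknown edit_type {self.edit_type!r}")

    @property
    def footprint_len(self) -> int:
        """Number of reference bases covered by the edit (0 for insertion)."""
        return len(self.ref_allele)

    @property
    def length_delta(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass(frozen=True)
class PegRNADesign:
    """pegRNA description: spacer, PAM pattern, PBS length, RT template, edit.

    ``rt_template`` is written 5'->3' as it appears in the pegRNA 3'
    extension (RNA or DNA alphabet); its reverse complement is the 3' DNA
    flap laid along the nicked strand from the nick.
    """

    spacer: str
    intended_edit: EditSpec
    pam_pattern: str = "NGG"
    pbs_len: int = 13
    rt_template: str = ""
    name: str = "pegRNA"

    def __post_init__(self):
        object.__setattr__(self, "spacer", self.spacer.upper().replace("U", "T"))
        object.__setattr__(self, "rt_template", self.rt_template.upper())
        if len(self.spacer) < 16:
            raise ValueError("spacer must be at least 16 nt")
        if self.pbs_len < 1:
            raise ValueError("pbs_len must be >= 1")


@dataclass(frozen=True)
class ProtospacerHit:
    """Location of the protospacer and PAM on the + strand of an amplicon."""

    start: int
    end: int
    strand: Literal["+", "-"]
    pam_start: int
    pam_end: int


@dataclass(frozen=True)
class QuantWindow:
    """Half-open quantification interval centred at the nick.

    ``span`` = [center - half_width, center + half_width), clipped to the
    amplicon and expanded (if needed) to contain the intended-edit footprint.
    """

    center: int
    half_width: int = 10
    start: int = field(default=-1)
    end: int = field(default=-1)

    def __post_init__(self):
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if self.start < 0 and self.end < 0:
            object.__setattr__(self, "start", self.center - self.half_width)
            object.__setattr__(self, "end", self.center + self.half_width)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def clipped(self, length: int) -> "QuantWindow":
        return QuantWindow(self.center, self.half_width,
                           max(0, self.start), min(length, self.end))

    def expanded_to(self, lo: int, hi: int) -> "QuantWindow":
        """Smallest window containing both the current span and [lo, hi)."""
        return QuantWindow(self.center, self.half_width,
                           min(self.start, lo), max(self.end, hi))

    def overlaps(self, lo: int, hi: int) -> bool:
        return max(self.start, lo) < min(self.end, hi)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def locate_protospacer(amplicon: AmpliconReference, design: PegRNADesign) -> ProtospacerHit:
    """Find the unique exact spacer+PAM occurrence on either strand.

    Coordinates are reported on the + strand.  Raises
    :class:`ProtospacerNotFound` / :class:`AmbiguousProtospacer`.
    """
    seq = amplicon.sequence
    spacer = design.spacer
    pam = _pam_regex(design.pam_pattern)
    plen = len(design.pam_pattern)
    hits: list[ProtospacerHit] = []

    for m in re.finditer(f"(?={re.escape(spacer)})", seq):
        s = m.start()
        e = s + len(spacer)
        if e + plen <= len(seq) and pam.fullmatch(seq, e, e + plen):
            hits.append(ProtospacerHit(s, e, "+", e, e + plen))

    rc_spacer = reverse_complement(spacer)
    rc_pam = _pam_regex(reverse_complement(design.pam_pattern))
    for m in re.finditer(f"(?={re.escape(rc_spacer)})", seq):
        s = m.start()  # protospacer occupies [s, e) in + coords
        e = s + len(spacer)
        if s - plen >= 0 and rc_pam.fullmatch(seq, s - plen, s):
            hits.append(ProtospacerHit(s, e, "-", s - plen, s))

    if not hits:
        raise ProtospacerNotFound(
            f"spacer {spacer} (PAM {design.pam_pattern}) not found in {amplicon.name}")
    if len(hits) > 1:
        raise AmbiguousProtospacer(
            f"spacer {spacer} matches {len(hits)} sites in {amplicon.name}")
    return hits[0]


def nick_position(hit: ProtospacerHit) -> int:
    """Cut coordinate of the Cas9 nick, 3 nt 5' of the PAM on the nicked strand.

    The nicked strand is cleaved between + strand positions ``c - 1`` and
    ``c``; for + strand hits ``c = pam_start - 3``, for - strand hits
    ``c = pam_end + 3``.
    """
    if hit.strand == "+":
        return hit.pam_start - 3
    return hit.pam_end + 3


def _edit_plus_coords(cut: int, strand: str, edit: EditSpec) -> tuple[int, int, str, str]:
    """Map an edit to + strand coordinates: (start, end, ref_plus, alt_plus).

    ``[start, end)`` is the replaced reference interval (empty for
    insertions, where ``start == end`` is the insertion point).
    """
    k = edit.position_rel_nick
    m = edit.footprint_len
    if strand == "+":
        if edit.edit_type == "insertion":
            start = end = cut + k - 1
        else:
            start = cut + k - 1
            end = start + m
        ref_plus, alt_plus = edit.ref_allele, edit.alt_allele
    else:
        # The nicked strand runs 3' toward decreasing + coordinates: nicked
        # position +k sits at + coordinate cut - k.
        if edit.edit_type == "insertion":
            start = end = cut - k + 1
        else:
            start = cut - k - m + 1
            end = cut - k + 1
        ref_plus = reverse_complement(edit.ref_allele)
        alt_plus = reverse_complement(edit.alt_allele)
    return start, end, ref_plus, alt_plus


def build_edited_allele(amplicon: AmpliconReference, cut: int, strand: str,
                        edit: EditSpec) -> str:
    """Expected intended-edit amplicon sequence on the + strand."""
    seq = amplicon.sequence
    start, end, ref_plus, alt_plus = _edit_plus_coords(cut, strand, edit)
    if start < 0 or end > len(seq) or start > end:
        raise OutOfBounds(
            f"edit footprint [{start},{end}) outside amplicon of length {len(seq)}")
    if ref_plus and seq[start:end] != ref_plus:
        raise RefMismatch(
            f"amplicon has {seq[start:end]!r} at [{start},{end}), edit expects {ref_plus!r}")
    return seq[:start] + alt_plus + seq[end:]


def edit_windows(amplicon: AmpliconReference, cut: int, strand: str, edit: EditSpec,
                 half_width: int = 10) -> tuple[QuantWindow, QuantWindow]:
    """Quantification windows on the reference and on the edited allele.

    The reference window is centred at the nick, clipped to the amplicon and
    expanded to contain the intended-edit footprint.  The edited-allele
    window covers the same region with the edit's length change applied, so
    a window indel means the same thing on either allele.
    """
    start, end, _, alt_plus = _edit_plus_coords(cut, strand, edit)
    win = QuantWindow(cut, half_width).clipped(len(amplicon))
    lo = max(0, min(start, end - 1)) if end > start else max(0, start)
    hi = min(len(amplicon), max(end, start + 1))
    win = win.expanded_to(min(win.start, lo), max(win.end, hi))
    win = win.clipped(len(amplicon))
    delta = edit.length_delta
    hdr_win = QuantWindow(win.center, win.half_width, win.start, win.end + delta)
    return win, hdr_win
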