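"""Off-target prime-editing quantification by 3'-flap walking.

At an off-target site the reverse-transcribed 3' DNA flap is identical to
the genomic sequence for some distance 3' of the nick; the first position
where the flap differs from the off-target amplicon is the *diagnostic
nucleotide*.  Reads carrying the flap base at that position are off-target
converted reads.  The off-target editing frequency is

    (converted reads + window-indel reads) / aligned reads

with indel-containing reads excluded from base calling (a read counts once,
as an indel read, when it is both).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .align import AlignParams
from .design import (AmpliconReference, OutOfBounds, PegRNADesign, ProtospacerHit,
                     QuantWindow, nick_position, reverse_complement)
from .quantify import (ReadRecord, ZeroAligned, align_and_assign,
                       classify_read, passes_quality, ReadClass)

__all__ = ["DiagnosticSite", "EmptyTemplate", "FlapSequence", "NoDiagnosticSite",
           "OffTargetTally", "find_diagnostic_site", "flap_from_design",
           "offtarget_frequency", "quantify_offtarget"]


class EmptyTemplate(ValueError):
    """The pegRNA has no RT template to derive a flap from."""


class NoDiagnosticSite(ValueError):
    """The flap matches the amplicon along its whole length."""


@dataclass(frozen=True)
class FlapSequence:
    """DNA copy of the RT template, 5'->3' along the nicked strand from the nick."""

    seq: str

    def __post_init__(self):
        if not self.seq:
            raise EmptyTemplate("empty 3' DNA flap")
        if not set(self.seq) <= set("ACGT"):
            raise ValueError("flap must be plain DNA over ACGT")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DiagnosticSite:
    """First flap/amplicon mismatch 3' of the nick (0-based offset)."""

    offset: int
    expected_base: str   # flap base, nicked-strand orientation
    ref_base: str        # amplicon base at the same position, nicked strand

    def __post_init__(self):
        if self.expected_base == self.ref_base:
            raise ValueError("diagnostic site must differ between flap and reference")


@dataclass(frozen=True)
class OffTargetTally:
    n_aligned: int
    n_converted: int
    n_indel: int

    @property
    def f_offtarget(self) -> float:
        if self.n_aligned == 0:
            raise ZeroAligned("no read aligned to the off-target amplicon")
        return (self.n_converted + self.n_indel) / self.n_aligned


def flap_from_design(design: PegRNADesign) -> FlapSequence:
    """3' DNA flap: reverse complement of the RT template (U pairs as A)."""
    if not design.rt_template:
        raise EmptyTemplate(f"{design.name} has no RT template")
    return FlapSequence(reverse_complement(design.rt_template))


def find_diagnostic_site(amplicon: AmpliconReference, cut: int, strand: str,
                         flap: FlapSequence) -> DiagnosticSite:
    """Walk the flap along the nicked strand from the nick to the first mismatch.

    Compares ``flap[i]`` with the amplicon base ``i`` nt 3' of the nick on
    the nicked strand for i = 0, 1, 2, ...; returns the first mismatching
    position.  An amplicon N counts as a mismatch (a candidate diagnostic
    site) unless the flap base is also N-like.
    """
    seq = amplicon.sequence
    for i, fb in enumerate(flap.seq):
        if strand == "+":
            pos = cut + i
            if pos >= len(seq):
                raise OutOfBounds("off-target amplicon ends before the flap mismatches")
            rb = seq[pos]
        else:
            pos = cut - 1 - i
            if pos < 0:
                raise OutOfBounds("off-target amplicon ends before the flap mismatches")
            rb = reverse_complement(seq[pos])
        if rb != fb:
            return DiagnosticSite(i, fb, rb)
    raise NoDiagnosticSite(
        "flap is a prefix of the off-target sequence; no diagnostic nucleotide")


def _site_plus_coord(cut: int, strand: str, site: DiagnosticSite) -> int:
    return cut + site.offset if strand == "+" else cut - 1 - site.offset


def offtarget_frequency(assignments, site: DiagnosticSite, window: QuantWindow,
                        cut: int, strand: str,
                        params: AlignParams = AlignParams()) -> OffTargetTally:
    """Tally converted and window-indel reads from single-allele assignments.

    ``assignments`` are :class:`~pegquant.quantify.ReadAssignment` objects
    produced against the off-target reference only.  A read with a window
    indel is counted in ``n_indel`` and excluded from base calling; an
    indel-free read is converted iff its base at the diagnostic coordinate
    equals the expected flap base (N never counts as converted).
    """
    pos = _site_plus_coord(cut, strand, site)
    n_aligned = n_converted = n_indel = 0
    for asn in assignments:
        if asn.assigned is None:
            continue
        n_aligned += 1
        cls = classify_read(asn, window, params)
        if cls in (ReadClass.REF_INDEL, ReadClass.HDR_INDEL):
            n_indel += 1
            continue
        base = asn.read_seq[pos] if asn.gapless else asn.alignment.read_base_at(pos)
        if base is None or base == "N":
            continue
        if strand == "-":
            base = reverse_complement(base)
        if base == site.expected_base:
            n_converted += 1
    return OffTargetTally(n_aligned, n_converted, n_indel)


def quantify_offtarget(reads: Iterable[ReadRecord], amplicon: AmpliconReference,
                       design: PegRNADesign, hit: ProtospacerHit,
                       min_mean_q: float = 30.0, half_width: int = 10,
                       params: AlignParams = AlignParams()):
    """Full off-target pipeline for one amplicon.

    The off-target protospacer ``hit`` is supplied by the caller (off-target
    protospacers generally mismatch the spacer, so exact spacer search does
    not locate them); reuse :func:`~pegquant.design.locate_protospacer` when
    the site does match exactly.
    """
    cut = nick_position(hit)
    flap = flap_from_design(design)
    site = find_diagnostic_site(amplicon, cut, hit.strand, flap)
    window = QuantWindow(cut, half_width).clipped(len(amplicon))

    def _gen():
        for read in reads:
            if not passes_quality(read, min_mean_q):
                continue
            # single-allele mode: both candidates are the off-target reference
            yield align_and_assign(read, amplicon.sequence, amplicon.sequence,
                                   window, window, params)

    t = offtarget_frequency(_gen(), site, window, cut, hit.strand, params)
    return site, window, t
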