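"""Small-RNA fragment integrity analysis for pegRNAs.

Paired-end small-RNA sequencing of expressed pegRNAs yields *fragments*
(intervals spanned by properly paired, sense-strand read pairs on the
pegRNA reference).  Fragments report on pegRNA integrity in cells: a
pegRNA needs its 3' extension to template reverse transcription and its
spacer 5' end to program the effector complex.  Fragments are therefore
binned as

* CIS_ACTIVE   — 5' end and 3' extension both intact (can edit in cis),
* TRANS_ACTIVE — 3' extension intact but 5' end lost,
* INACTIVE     — 3' extension truncated,

with start/end tolerances as explicit parameters.  The module also
implements closest-endpoint annotation assignment (for overlapping
annotations), per-position coverage, and a 3'-intactness summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = ["AnnotationSet", "EmptyInput", "Fragment", "FragmentBin", "NoOverlap",
           "PegRegionMap", "assign_fragment", "bin_fragment", "bin_fragments",
           "coverage_profile", "three_prime_intact_fraction"]


class NoOverlap(ValueError):
    """Fragment overlaps no annotation."""


class EmptyInput(ValueError):
    """No fragments supplied."""


@dataclass(frozen=True)
class Fragment:
    """A sequenced fragment interval (0-based, half-open) on a reference."""

    reference: str
    start: int
    end: int
    strand: str = "+"
    proper_pair: bool = True

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid fragment interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotationSet:
    """Named half-open intervals on a common reference (unique names)."""

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        names = [n for n, _, _ in self.intervals]
        if len(set(names)) != len(names):
            raise ValueError("annotation names must be unique")
        for n, s, e in self.intervals:
            if not 0 <= s < e:
                raise ValueError(f"invalid annotation {n}: [{s},{e})")


@dataclass(frozen=True)
class PegRegionMap:
    """pegRNA anatomy: 5'->3' regions tiling [0, L) plus binning tolerances.

    ``regions`` maps region name (spacer, scaffold, rt_template, pbs and an
    optional 3' motif/polyU) to its half-open interval.  ``start_tol`` /
    ``end_tol`` are the number of terminal nucleotides that may be missing
    while the corresponding end still counts as intact.
    """

    length: int
    regions: tuple[tuple[str, int, int], ...]
    start_tol: int = 3
    end_tol: int = 3

    def __post_init__(self):
        pos = 0
        for name, s, e in self.regions:
            if s != pos or e <= s:
                raise ValueError(
                    f"regions must tile [0,{self.length}) in order; {name} is [{s},{e})")
            pos = e
        if pos != self.length:
            raise ValueError(f"regions end at {pos}, expected {self.length}")

    @classmethod
    def from_lengths(cls, spacer: int = 20, scaffold: int = 76, rt_template: int = 13,
                     pbs: int = 13, motif: int = 0, polyu: int = 0,
                     start_tol: int = 3, end_tol: int = 3) -> "PegRegionMap":
        parts = [("spacer", spacer), ("scaffold", scaffold),
                 ("rt_template", rt_template), ("pbs", pbs)]
        if motif:
            parts.append(("motif", motif))
        if polyu:
            parts.append(("polyu", polyu))
        regions, pos = [], 0
        for name, ln in parts:
            regions.append((name, pos, pos + ln))
            pos += ln
        return cls(pos, tuple(regions), start_tol, end_tol)


class FragmentBin(Enum):
    CIS_ACTIVE = "cis_active"
    TRANS_ACTIVE = "trans_active"
    INACTIVE = "inactive"


def assign_fragment(frag: Fragment, annotations: AnnotationSet) -> str:
    """Assign a fragment to the annotation with the closest start and end.

    Distance is |frag.start - ann.start| + |frag.end - ann.end| over
    annotations the fragment overlaps; ties break to the shorter
    annotation, then lexicographically by name.
    """
    best = None
    for name, s, e in annotations.intervals:
        if max(frag.start, s) >= min(frag.end, e):
            continue
        d = abs(frag.start - s) + abs(frag.end - e)
        key = (d, e - s, name)
        if best is None or key < best:
            best = key
    if best is None:
        raise NoOverlap(
            f"fragment [{frag.start},{frag.end}) overlaps no annotation")
    return best[2]


def bin_fragment(frag: Fragment, regions: PegRegionMap) -> FragmentBin:
    """Three-bin activity classification of a pegRNA fragment.

    CIS_ACTIVE: start <= start_tol and end >= L - end_tol (both ends intact);
    TRANS_ACTIVE: 3' end intact but 5' end lost; INACTIVE: 3' end truncated.
    """
    three_intact = frag.end >= regions.length - regions.end_tol
    five_intact = frag.start <= regions.start_tol
    if three_intact and five_intact:
        return FragmentBin.CIS_ACTIVE
    if three_intact:
        return FragmentBin.TRANS_ACTIVE
    return FragmentBin.INACTIVE


def bin_fragments(frags: Iterable[Fragment], regions: PegRegionMap,
                  require_proper_sense: bool = True) -> dict:
    """Bin counts over eligible (proper-pair, sense-strand) fragments."""
    counts = {b: 0 for b in FragmentBin}
    for f in frags:
        if require_proper_sense and not (f.proper_pair and f.strand == "+"):
            continue
        counts[bin_fragment(f, regions)] += 1
    return counts


def coverage_profile(frags: Sequence[Fragment], length: int) -> np.ndarray:
    """Per-position fragment coverage over [0, length).

    coverage[p] = number of fragments with start <= p < end; the vector sums
    to the total fragment length, exactly.
    """
    cov = np.zeros(length, dtype=np.int64)
    delta = np.zeros(length + 1, dtype=np.int64)
    for f in frags:
        if f.start < 0 or f.end > length:
            raise ValueError(
                f"fragment [{f.start},{f.end}) outside reference of length {length}")
        delta[f.start] += 1
        delta[f.end] -= 1
    np.cumsum(delta[:-1], out=cov)
    return cov


def three_prime_intact_fraction(frags: Sequence[Fragment], length: int,
                                tol: int = 3) -> float:
    """Fraction of fragments whose 3' end reaches within ``tol`` of the end."""
    frags = list(frags)
    if not frags:
        raise EmptyInput("no fragments")
    n = sum(1 for f in frags if f.end >= length - tol)
    return n / len(frags)
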