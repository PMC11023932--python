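"""Seeded synthetic data with the statistical structure each analysis assumes.

Three generators, one per analysis stage:

* :func:`sim_amplicon_reads` — amplicon reads drawn from a programmed
  mixture of outcome classes (intended edit without/with window indel,
  window indel only, unedited) plus i.i.d. substitution sequencing error;
* :func:`sim_screen` — sgRNA count tables with log-normal library
  abundances, negative-binomial sampling and planted enrichment effects;
* :func:`sim_fragments` — pegRNA fragments with programmed bin proportions
  or a geometric 5'/3' truncation model.

Every generator takes an explicit seed, uses one ``numpy`` Generator per
call (no global state) and returns a truth table sufficient to score
recovery without re-deriving the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (AmpliconReference, PegRNADesign, QuantWindow,
                     build_edited_allele, edit_windows, locate_protospacer,
                     nick_position)
from .integrity import Fragment, PegRegionMap
from .quantify import ReadClass, ReadRecord

__all__ = ["FragmentSimConfig", "OutcomeMixture", "ScreenSimConfig",
           "random_amplicon", "sim_amplicon_reads", "sim_fragments",
           "sim_screen"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class OutcomeMixture:
    """Programmed outcome-class proportions and the read error model.

    ``proportions`` are for (HDR_CLEAN, HDR_INDEL, REF_INDEL, REF_CLEAN).
    Window indels are drawn uniform 1-5 nt with deletions twice as likely
    as insertions, matching where nick-between-nicks indels concentrate.
    """

    proportions: tuple[float, float, float, float] = (0.25, 0.05, 0.10, 0.60)
    error_rate: float = 0.001
    indel_len_range: tuple[int, int] = (1, 5)
    deletion_fraction: float = 2 / 3

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be non-negative and sum to 1")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error rate must be in [0, 0.05]")


def random_amplicon(length: int = 200, seed: int = 0,
                    name: str = "amplicon") -> AmpliconReference:
    """Uniform-random DNA amplicon, for fixtures and simulations."""
    rng = np.random.default_rng(seed)
    seq = bytes(rng.choice(_BASES, size=length)).decode()
    return AmpliconReference(name, seq)


def _shift_range_deletion(seq: str, start: int, length: int) -> tuple[int, int]:
    """Leftmost/rightmost equivalent start for deleting seq[start:start+length].

    A deletion can slide one position left when the base entering the gap
    from the left equals the base leaving on the right (homopolymer/repeat
    normalization); the returned closed range is where any optimal
    alignment may place it.
    """
    lo = start
    while lo > 0 and seq[lo - 1] == seq[lo + length - 1]:
        lo -= 1
    hi = start
    while hi + length < len(seq) and seq[hi] == seq[hi + length]:
        hi += 1
    return lo, hi


def _shift_range_insertion(seq: str, anchor: int, ins: str) -> tuple[int, int]:
    """Anchor range over which an insertion after ``anchor`` can slide."""
    lo = anchor
    k = len(ins)
    while lo >= 0 and seq[lo] == ins[(lo - anchor - 1) % k]:
        lo -= 1
    hi = anchor
    while hi + 1 < len(seq) and seq[hi + 1] == ins[(hi - anchor) % k]:
        hi += 1
    return lo, hi


def _draw_window_indel(rng, allele: str, window: QuantWindow, mixture: OutcomeMixture,
                       avoid: tuple[int, int] | None):
    """Pick an indel whose every equivalent placement stays in the window.

    Returns (kind, pos, payload): deletion removes allele[pos:pos+len];
    insertion places bases after anchor pos.  ``avoid`` is a half-open
    allele interval (the intended-edit footprint) the indel must not touch,
    so the programmed truth class is actually realized in the read.
    """
    lmin, lmax = mixture.indel_len_range
    for _ in range(200):
        length = int(rng.integers(lmin, lmax + 1))
        if rng.random() < mixture.deletion_fraction:
            start = int(rng.integers(window.start, window.end))
            if start + length > len(allele):
                continue
            if avoid and max(start, avoid[0]) < min(start + length, avoid[1]):
                continue
            lo, hi = _shift_range_deletion(allele, start, length)
            if lo < window.start or hi + length > window.end:
                continue
            if avoid and max(lo, avoid[0]) < min(hi + length, avoid[1]):
                continue
            return "del", start, length
        else:
            anchor = int(rng.integers(window.start, window.end))
            ins = bytes(rng.choice(_BASES, size=length)).decode()
            if avoid and avoid[0] <= anchor < avoid[1] - 1:
                continue
            lo, hi = _shift_range_insertion(allele, anchor, ins)
            if lo < window.start or hi >= window.end:
                continue
            return "ins", anchor, ins
    raise RuntimeError("could not place a window indel; window too constrained")


def _apply_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def sim_amplicon_reads(amplicon: AmpliconReference, design: PegRNADesign,
                       mixture: OutcomeMixture = OutcomeMixture(), n: int = 10_000,
                       seed: int = 0, half_width: int = 10, phred: int = 37,
                       random_quals: bool = False):
    """Simulate amplicon reads from the programmed outcome mixture.

    Each read's class is drawn from the mixture; the read starts from the
    corresponding allele (reference or intended-edit), window-indel classes
    get one indel placed uniformly in the quantification window, and i.i.d.
    substitution errors are applied last.  Returns (reads, truth) where
    truth is a DataFrame with the programmed class per read.
    """
    rng = np.random.default_rng(seed)
    hit = locate_protospacer(amplicon, design)
    cut = nick_position(hit)
    hdr_seq = build_edited_allele(amplicon, cut, hit.strand, design.intended_edit)
    ref_win, hdr_win = edit_windows(amplicon, cut, hit.strand,
                                    design.intended_edit, half_width)
    from .design import _edit_plus_coords
    fs, fe, _, alt_plus = _edit_plus_coords(cut, hit.strand, design.intended_edit)
    # footprint to protect on each allele (edit interval on HDR coordinates)
    hdr_avoid = (fs, fs + max(1, len(alt_plus)))
    order = [ReadClass.HDR_CLEAN, ReadClass.HDR_INDEL,
             ReadClass.REF_INDEL, ReadClass.REF_CLEAN]
    classes = rng.choice(4, size=n, p=np.asarray(mixture.proportions))
    reads, rows = [], []
    for i, ci in enumerate(classes):
        cls = order[ci]
        if cls in (ReadClass.HDR_CLEAN, ReadClass.HDR_INDEL):
            allele, window, avoid = hdr_seq, hdr_win, hdr_avoid
        else:
            allele, window, avoid = amplicon.sequence, ref_win, None
        seq = allele
        if cls in (ReadClass.HDR_INDEL, ReadClass.REF_INDEL):
            kind, pos, payload = _draw_window_indel(rng, allele, window, mixture, avoid)
            if kind == "del":
                seq = allele[:pos] + allele[pos + payload:]
            else:
                seq = allele[:pos + 1] + payload + allele[pos + 1:]
        seq = _apply_errors(rng, seq, mixture.error_rate)
        if random_quals:
            # per-read quality level spanning the q30 filter, per-base jitter
            level = int(rng.integers(20, 41))
            quals = tuple(int(q) for q in
                          np.clip(rng.integers(level - 3, level + 4, size=len(seq)),
                                  2, 41))
        else:
            quals = tuple([phred] * len(seq))
        rid = f"read{i:06d}"
        reads.append(ReadRecord(rid, seq, quals))
        rows.append((rid, cls.value))
    truth = pd.DataFrame(rows, columns=["read_id", "true_class"])
    return reads, truth


def random_editing_locus(length: int = 200, seed: int = 0, edit_position: int = 7,
                         edit_len: int = 2, rt_len: int = 13,
                         edit_type: str = "substitution", alt: str | None = None):
    """Random amplicon with a unique spacer+PAM and a matched pegRNA design.

    The protospacer sits mid-amplicon on the + strand with an NGG PAM; the
    default intended edit is a 2-bp substitution at +7 (the reporter-style
    GG-to-CA geometry); the RT template is chosen so the 3' DNA flap copies
    the edited strand for ``rt_len`` nt from the nick.
    """
    from .design import EditSpec, reverse_complement

    for attempt in range(50):
        rng = np.random.default_rng(seed + 1_000_003 * attempt)
        arr = rng.choice(_BASES, size=length)
        pam_start = length // 2
        arr[pam_start + 1] = ord("G")
        arr[pam_start + 2] = ord("G")
        seq = arr.tobytes().decode()
        cut = pam_start - 3
        k = edit_position
        if edit_type == "substitution":
            ref = seq[cut + k - 1:cut + k - 1 + edit_len]
            if alt is None:
                # transversion of each footprint base
                swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
                alt_allele = "".join(swap[b] for b in ref)
            else:
                alt_allele = alt
            edit = EditSpec("substitution", k, ref, alt_allele)
        elif edit_type == "insertion":
            edit = EditSpec("insertion", k, "", alt or "CAT")
        else:
            ref = seq[cut + k - 1:cut + k - 1 + edit_len]
            edit = EditSpec("deletion", k, ref, "")
        amplicon = AmpliconReference("locus", seq)
        hdr = build_edited_allele(amplicon, cut, "+", edit)
        flap = hdr[cut:cut + rt_len]
        design = PegRNADesign(spacer=seq[pam_start - 20:pam_start],
                              intended_edit=edit,
                              rt_template=reverse_complement(flap),
                              name="sim-pegRNA")
        try:
            hit = locate_protospacer(amplicon, design)
        except Exception:
            continue
        if nick_position(hit) == cut:
            return amplicon, design
    raise RuntimeError("could not construct a unique editing locus")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Synthetic pooled-screen design.

    Defaults emulate a genome-scale CRISPRi library (5 sgRNAs per gene)
    screened at 500x depth per sorted population.  ``planted`` maps gene
    name -> log2 effect on marker-positive abundance; ``active_per_gene``
    of that gene's sgRNAs carry the effect.  ``dispersion`` is the
    negative-binomial size parameter (variance = m + m^2 / size);
    ``np.inf`` gives the Poisson limit.
    """

    n_genes: int = 18_905
    sgrnas_per_gene: int = 5
    n_nt: int = 3_751
    depth: float = 500.0
    abundance_sigma: float = 0.5
    dispersion: float = 30.0
    planted: dict = field(default_factory=dict)
    active_per_gene: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0 or self.dispersion <= 0:
            raise ValueError("depth and dispersion must be positive")
        if self.planted and not np.all(np.isfinite(list(self.planted.values()))):
            raise ValueError("planted effects must be finite")
        if not 1 <= self.active_per_gene <= self.sgrnas_per_gene:
            raise ValueError("active_per_gene must be in [1, sgrnas_per_gene]")


def _nb_draw(rng, mean: np.ndarray, size_param: float) -> np.ndarray:
    if np.isinf(size_param):
        return rng.poisson(mean)
    lam = rng.gamma(shape=size_param, scale=mean / size_param)
    return rng.poisson(lam)


def sim_screen(config: ScreenSimConfig):
    """Simulate a sorted-screen count table. Returns (table, truth).

    Library abundance is log-normal (normalized to mean 1); the
    marker-negative expectation is depth x abundance for every sgRNA; the
    marker-positive expectation multiplies in 2^effect for planted, active
    sgRNAs.  Counts are negative-binomial.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    ids, gene_col, tss_col, nt_col = [], [], [], []
    for g in genes:
        for j in range(config.sgrnas_per_gene):
            ids.append(f"{g}_sg{j}")
            gene_col.append(g)
            tss_col.append("P1")
            nt_col.append(False)
    for j in range(config.n_nt):
        ids.append(f"nt_sg{j:05d}")
        gene_col.append("non-targeting")
        tss_col.append("NA")
        nt_col.append(True)
    n = len(ids)
    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    abundance /= np.exp(config.abundance_sigma ** 2 / 2)  # mean 1
    effect = np.zeros(n)
    planted_rows = []
    for g, eff in config.planted.items():
        gi = genes.index(g)
        base = gi * config.sgrnas_per_gene
        active = rng.choice(config.sgrnas_per_gene, size=config.active_per_gene,
                            replace=False)
        for j in active:
            effect[base + j] = eff
        planted_rows.append((g, eff, config.active_per_gene))
    mean_neg = config.depth * abundance
    mean_pos = mean_neg * np.exp2(effect)
    table = pd.DataFrame({
        "sgrna_id": ids, "gene": gene_col, "tss": tss_col,
        "non_targeting": nt_col,
        "count_pos": _nb_draw(rng, mean_pos, config.dispersion),
        "count_neg": _nb_draw(rng, mean_neg, config.dispersion),
    })
    truth = pd.DataFrame(planted_rows, columns=["gene", "effect", "n_active"])
    return table, truth


@dataclass(frozen=True)
class FragmentSimConfig:
    """pegRNA fragment generator: programmed bins or geometric truncation.

    With ``bin_proportions`` set, fragments are drawn per bin (endpoints
    uniform within the bin's constraints).  Otherwise 5'/3' truncation
    lengths are truncated-geometric with per-base survival 1 - p.
    """

    length: int = 122
    n: int = 10_000
    bin_proportions: tuple[float, float, float] | None = (0.6, 0.1, 0.3)
    p_trunc_5: float = 0.02
    p_trunc_3: float = 0.02
    start_tol: int = 3
    end_tol: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.bin_proportions is not None:
            p = np.asarray(self.bin_proportions, dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("bin proportions must be non-negative and sum to 1")
        for p in (self.p_trunc_5, self.p_trunc_3):
            if not 0 < p <= 1:
                raise ValueError("truncation probabilities must be in (0, 1]")


def truncated_geometric_mean(p: float, max_t: int) -> float:
    """Mean of a geometric(support 0,1,...) conditioned on <= max_t.

    Computed by direct summation; used as the closed-form expectation for
    the truncation model.
    """
    t = np.arange(max_t + 1)
    w = p * (1 - p) ** t
    return float((t * w).sum() / w.sum())


def _draw_trunc(rng, p: float, max_t: int, size: int) -> np.ndarray:
    """Truncated-geometric truncation lengths via inverse CDF."""
    u = rng.random(size)
    zmax = 1 - (1 - p) ** (max_t + 1)
    return np.minimum(np.floor(np.log1p(-u * zmax) / np.log1p(-p)).astype(int), max_t)


def sim_fragments(config: FragmentSimConfig, reference: str = "pegRNA"):
    """Simulate pegRNA fragments. Returns (fragments, truth DataFrame)."""
    rng = np.random.default_rng(config.seed)
    L, n = config.length, config.n
    st, et = config.start_tol, config.end_tol
    frags, rows = [], []
    if config.bin_proportions is not None:
        bins = rng.choice(3, size=n, p=np.asarray(config.bin_proportions))
        for i, b in enumerate(bins):
            if b == 0:  # cis-active: both ends within tolerance
                s = int(rng.integers(0, st + 1))
                e = int(L - rng.integers(0, et + 1))
                label = "cis_active"
            elif b == 1:  # trans-active: 3' intact, 5' lost
                s = int(rng.integers(st + 1, L - et - 1))
                e = int(L - rng.integers(0, et + 1))
                label = "trans_active"
            else:  # inactive: 3' truncated
                e = int(rng.integers(2, L - et))
                s = int(rng.integers(0, e))
                label = "inactive"
            frags.append(Fragment(reference, s, e))
            rows.append((i, s, e, label))
    else:
        t5 = _draw_trunc(rng, config.p_trunc_5, L - 2, n)
        t3 = _draw_trunc(rng, config.p_trunc_3, L - 2, n)
        for i in range(n):
            s = int(t5[i])
            e = int(L - t3[i])
            if s >= e:  # degenerate double truncation: redraw singly
                s, e = 0, L
            frag = Fragment(reference, s, e)
            three = e >= L - et
            five = s <= st
            label = ("cis_active" if three and five
                     else "trans_active" if three else "inactive")
            frags.append(frag)
            rows.append((i, s, e, label))
    truth = pd.DataFrame(rows, columns=["fragment", "start", "end", "true_bin"])
    return frags, truth
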