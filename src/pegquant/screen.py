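"""Reporter-screen enrichment statistics for pooled CRISPRi screens.

The screen separates reporter-positive from reporter-negative cells and
sequences the integrated sgRNA cassettes from both sorted populations.
Analysis proceeds sgRNA -> gene -> significance:

1. a read-count floor of 50 is imposed per sgRNA within each sample;
2. each sgRNA's phenotype is the log2 enrichment of its total-count
   normalized abundance in the marker-positive over the marker-negative
   population, centred so that the non-targeting (NT) median is 0;
3. each gene/TSS score averages the signed phenotypes of its strongest
   k = 3 sgRNAs by absolute value;
4. "pseudogenes" of five randomly grouped NT sgRNAs provide the empirical
   null, from which a plus-one-corrected empirical p-value and a
   Benjamini–Hochberg FDR are computed.  An export function writes the
   sgRNA phenotype table for the external hierarchical mixture-model tool
   (CRISPhieRmix); that external fit is not performed here.

Count tables are pandas DataFrames with columns
``sgrna_id, gene, tss, non_targeting, count_pos, count_neg``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["NoNonTargeting", "PseudogeneSet", "TooFewNT", "TooFewPseudogenes",
           "apply_count_floor", "empirical_fdr", "export_for_crisphiermix",
           "gene_scores", "make_pseudogenes", "pseudogene_scores",
           "sgrna_phenotypes", "validate_count_table"]

REQUIRED_COLUMNS = ["sgrna_id", "gene", "tss", "non_targeting",
                    "count_pos", "count_neg"]


class NoNonTargeting(ValueError):
    """The table has no non-targeting sgRNAs to centre on."""


class TooFewNT(ValueError):
    """Not enough non-targeting sgRNAs to build a pseudogene."""


class TooFewPseudogenes(ValueError):
    """Too few pseudogene scores for a usable empirical null."""


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if (table[["count_pos", "count_neg"]] < 0).any().any():
        raise ValueError("counts must be non-negative")
    if not table["non_targeting"].astype(bool).any():
        raise NoNonTargeting("count table has no non-targeting sgRNAs")
    targeting = table.loc[~table["non_targeting"].astype(bool)]
    if targeting["gene"].isna().any() or (targeting["gene"] == "").any():
        raise ValueError("targeting sgRNAs need a gene label")
    return table


def apply_count_floor(table: pd.DataFrame, floor: int = 50,
                      mode: str = "floor") -> pd.DataFrame:
    """Impose the per-sample read-count minimum.

    ``mode='floor'`` (default) raises every count below ``floor`` to
    ``floor`` in each sample independently, preserving the library;
    ``mode='filter'`` instead drops rows below the floor in both samples
    (sensitivity-analysis variant).
    """
    out = table.copy()
    if mode == "floor":
        out["count_pos"] = out["count_pos"].clip(lower=floor)
        out["count_neg"] = out["count_neg"].clip(lower=floor)
    elif mode == "filter":
        keep = (out["count_pos"] >= floor) & (out["count_neg"] >= floor)
        out = out.loc[keep].reset_index(drop=True)
    else:
        raise ValueError("mode must be 'floor' or 'filter'")
    return out


def sgrna_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """sgRNA-level log2 enrichment, centred on the non-targeting median.

    r = log2((count_pos / total_pos) / (count_neg / total_neg));
    phenotype = r - median(r over NT sgRNAs).  Invariant under rescaling of
    either sample's counts; NT median phenotype is exactly 0.
    """
    validate_count_table(table)
    total_pos = float(table["count_pos"].sum())
    total_neg = float(table["count_neg"].sum())
    if total_pos <= 0 or total_neg <= 0:
        raise ValueError("both samples need positive totals")
    r = (np.log2(table["count_pos"].to_numpy(dtype=float) / total_pos)
         - np.log2(table["count_neg"].to_numpy(dtype=float) / total_neg))
    nt = table["non_targeting"].astype(bool).to_numpy()
    phen = r - np.median(r[nt])
    # re-centre once: with an even NT count the first pass can leave the
    # median a rounding error away from zero
    phen = phen - np.median(phen[nt])
    out = table[["sgrna_id", "gene", "tss", "non_targeting"]].copy()
    out["phenotype"] = phen
    return out


def _top_k_mean(values: np.ndarray, k: int) -> tuple[float, int]:
    """Signed mean of the k strongest values by absolute value."""
    if len(values) <= k:
        return float(np.mean(values)), len(values)
    idx = np.argsort(-np.abs(values), kind="stable")[:k]
    return float(np.mean(values[idx])), k


def gene_scores(phenotypes: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Per-TSS gene scores: signed mean of the k strongest sgRNA phenotypes.

    Rows of the result are (gene, tss); genes with multiple TSSs also carry
    ``gene_score``, the TSS score of largest magnitude for that gene.
    """
    targ = phenotypes.loc[~phenotypes["non_targeting"].astype(bool),
                          ["gene", "tss", "phenotype"]].copy()
    keys = pd.MultiIndex.from_frame(targ[["gene", "tss"]])
    codes = keys.factorize(sort=True)[0]
    targ["_code"] = codes
    targ["_abs"] = targ["phenotype"].abs()
    # strongest-k selection: stable sort by |phenotype| within each TSS group
    targ = targ.sort_values(["_code", "_abs"], ascending=[True, False],
                            kind="stable")
    rank = targ.groupby("_code").cumcount()
    sel = targ.loc[rank.to_numpy() < k]
    agg = sel.groupby("_code").agg(gene=("gene", "first"), tss=("tss", "first"),
                                   score=("phenotype", "mean"),
                                   n_sgrnas_used=("phenotype", "size"))
    out = agg.reset_index(drop=True)
    out["n_sgrnas_used"] = out["n_sgrnas_used"].astype(int)
    best = (out.loc[out.groupby("gene")["score"].transform(lambda s: s.abs().idxmax())
                    .to_numpy(), "score"])
    out["gene_score"] = best.to_numpy()
    return out


@dataclass(frozen=True)
class PseudogeneSet:
    """Random groupings of non-targeting sgRNAs used as the empirical null."""

    groups: tuple[tuple[str, ...], ...]
    seed: int
    with_replacement: bool = False

    def __len__(self) -> int:
        return len(self.groups)


def make_pseudogenes(nt_ids, group_size: int = 5, n_pseudogenes: int | None = None,
                     seed: int = 0, with_replacement: bool = False) -> PseudogeneSet:
    """Group non-targeting sgRNAs into pseudogenes of ``group_size`` members.

    Default (auto) mode shuffles the NT sgRNAs and cuts
    floor(n_nt / group_size) disjoint groups; with-replacement resampling is
    available when NT sgRNAs are scarce (members are still unique within a
    group).
    """
    nt_ids = list(nt_ids)
    if len(nt_ids) < group_size:
        raise TooFewNT(f"{len(nt_ids)} non-targeting sgRNAs < group size {group_size}")
    rng = np.random.default_rng(seed)
    if with_replacement:
        if n_pseudogenes is None:
            raise ValueError("n_pseudogenes is required with replacement")
        # draw index matrix, redraw rows with within-group duplicates
        idx = rng.integers(0, len(nt_ids), size=(n_pseudogenes, group_size))
        while True:
            srt = np.sort(idx, axis=1)
            bad = np.flatnonzero((srt[:, 1:] == srt[:, :-1]).any(axis=1))
            if not len(bad):
                break
            idx[bad] = rng.integers(0, len(nt_ids), size=(len(bad), group_size))
        groups = tuple(tuple(nt_ids[i] for i in row) for row in idx)
    else:
        auto = len(nt_ids) // group_size
        n = auto if n_pseudogenes is None else n_pseudogenes
        if n > auto:
            raise TooFewNT(f"cannot cut {n} disjoint pseudogenes of {group_size} "
                           f"from {len(nt_ids)} non-targeting sgRNAs")
        perm = rng.permutation(len(nt_ids))
        groups = tuple(tuple(nt_ids[i] for i in perm[g * group_size:(g + 1) * group_size])
                       for g in range(n))
    return PseudogeneSet(groups, seed, with_replacement)


def pseudogene_scores(phenotypes: pd.DataFrame, pseudogenes: PseudogeneSet,
                      k: int = 3) -> np.ndarray:
    """Gene-style scores for each pseudogene (same top-k rule as real genes)."""
    phen = phenotypes.set_index("sgrna_id")["phenotype"]
    if not pseudogenes.groups:
        return np.empty(0)
    sizes = {len(g) for g in pseudogenes.groups}
    if len(sizes) == 1 and (size := sizes.pop()) > k:
        # vectorized top-k for the common fixed-size case
        ids = np.array([m for g in pseudogenes.groups for m in g])
        vals = phen.loc[ids].to_numpy().reshape(len(pseudogenes.groups), size)
        idx = np.argsort(-np.abs(vals), axis=1, kind="stable")[:, :k]
        return np.take_along_axis(vals, idx, axis=1).mean(axis=1)
    return np.array([_top_k_mean(phen.loc[list(g)].to_numpy(), k)[0]
                     for g in pseudogenes.groups])


def empirical_fdr(genes: pd.DataFrame, pseudo_scores: np.ndarray,
                  fdr_threshold: float = 0.01) -> pd.DataFrame:
    """Annotate gene scores with an empirical p-value and a BH FDR.

    empirical_p = (1 + #{pseudogenes with |score| >= |gene score|})
                  / (1 + n_pseudogenes), two-sided on magnitude with the
    plus-one correction; ``fdr`` is Benjamini–Hochberg over all rows and
    ``hit`` flags fdr <= ``fdr_threshold``.
    """
    pseudo = np.abs(np.asarray(pseudo_scores, dtype=float))
    if len(pseudo) < 20:
        raise TooFewPseudogenes(f"{len(pseudo)} pseudogenes < 20")
    out = genes.copy()
    mags = np.abs(out["score"].to_numpy(dtype=float))
    pseudo_sorted = np.sort(pseudo)
    n_ge = len(pseudo) - np.searchsorted(pseudo_sorted, mags, side="left")
    out["empirical_p"] = (1 + n_ge) / (1 + len(pseudo))
    out["fdr"] = multipletests(out["empirical_p"], method="fdr_bh")[1]
    out["hit"] = out["fdr"] <= fdr_threshold
    return out


def export_for_crisphiermix(phenotypes: pd.DataFrame, path) -> pd.DataFrame:
    """Write the sgRNA phenotype table for the external mixture-model tool.

    Columns: sgrna_id, gene, phenotype, non_targeting (NT rows flagged 1,
    gene label 'negative_control').  Returns the written frame.
    """
    out = phenotypes[["sgrna_id", "gene", "phenotype", "non_targeting"]].copy()
    out["non_targeting"] = out["non_targeting"].astype(bool).astype(int)
    out.loc[out["non_targeting"] == 1, "gene"] = "negative_control"
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return out


def analyze_screen(table: pd.DataFrame, floor: int = 50, k: int = 3,
                   group_size: int = 5, seed: int = 0,
                   fdr_threshold: float = 0.01, floor_mode: str = "floor",
                   n_pseudogenes: int | None = None,
                   with_replacement: bool = False):
    """Count table -> (sgRNA phenotypes, annotated gene table, pseudogene scores).

    The empirical p-value cannot go below 1/(n_pseudogenes + 1), so
    Benjamini–Hochberg hit calling at a strict threshold over many genes
    needs a large null: pass ``n_pseudogenes`` with ``with_replacement=True``
    to resample beyond the disjoint-group default.
    """
    floored = apply_count_floor(table, floor, mode=floor_mode)
    phen = sgrna_phenotypes(floored)
    genes = gene_scores(phen, k=k)
    nt_ids = phen.loc[phen["non_targeting"].astype(bool), "sgrna_id"]
    pseudo = make_pseudogenes(nt_ids, group_size=group_size, seed=seed,
                              n_pseudogenes=n_pseudogenes,
                              with_replacement=with_replacement)
    pscores = pseudogene_scores(phen, pseudo, k=k)
    annotated = empirical_fdr(genes, pscores, fdr_threshold)
    return phen, annotated, pscores
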