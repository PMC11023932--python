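"""Readers and writers for the formats the pipelines consume.

FASTA/FASTQ go through Biopython, tables through pandas, design and region
files through YAML, and optional SAM input through pysam.  Everything is
plain text.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO

from .design import AmpliconReference, EditSpec, PegRNADesign
from .integrity import Fragment, PegRegionMap
from .quantify import ReadRecord

__all__ = ["read_amplicons", "read_design", "read_fastq", "read_fragments_bed",
           "read_fragments_sam", "read_region_map", "read_screen_counts",
           "write_fastq", "write_fragments_bed", "write_screen_counts"]


def read_amplicons(path) -> list[AmpliconReference]:
    """Load amplicon references from a FASTA file."""
    return [AmpliconReference(rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq(path) -> list[ReadRecord]:
    """Load reads (Phred+33 qualities) from a FASTQ file."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = tuple(rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(rec.id, str(rec.seq).upper(), quals))
    return out


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.quals if r.quals is not None else (37,) * len(r.seq)
            qstr = "".join(chr(min(q, 93) + 33) for q in quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qstr}\n")


def read_design(path) -> tuple[PegRNADesign, dict]:
    """Load a pegRNA design from YAML.

    Required keys: spacer, edit_type, position_rel_nick and the relevant
    alleles; optional: pam_pattern, pbs_len, rt_template, window_half_width,
    name, protospacer (an explicit site sequence for off-target amplicons).
    Returns (design, extras) where extras holds the optional analysis keys.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    edit = EditSpec(edit_type=doc["edit_type"],
                    position_rel_nick=int(doc["position_rel_nick"]),
                    ref_allele=doc.get("ref_allele", "") or "",
                    alt_allele=doc.get("alt_allele", "") or "")
    design = PegRNADesign(spacer=doc["spacer"],
                          intended_edit=edit,
                          pam_pattern=doc.get("pam_pattern", "NGG"),
                          pbs_len=int(doc.get("pbs_len", 13)),
                          rt_template=doc.get("rt_template", "") or "",
                          name=doc.get("name", Path(str(path)).stem))
    extras = {k: doc[k] for k in ("window_half_width", "protospacer") if k in doc}
    return design, extras


def read_screen_counts(path) -> pd.DataFrame:
    """Load an sgRNA count TSV (sgrna_id, gene, tss, non_targeting, counts)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"sgrna_id": str, "gene": str, "tss": str})
    df["non_targeting"] = df["non_targeting"].astype(bool)
    return df


def write_screen_counts(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["non_targeting"] = out["non_targeting"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_fragments_bed(path) -> list[Fragment]:
    """Load fragments from BED3+ (chrom, start, end[, name, score, strand])."""
    frags = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 else "+"
            frags.append(Fragment(f[0], int(f[1]), int(f[2]), strand))
    return frags


def write_fragments_bed(frags: Iterable[Fragment], path) -> None:
    with open(path, "w") as fh:
        for i, f in enumerate(frags):
            fh.write(f"{f.reference}\t{f.start}\t{f.end}\tfrag{i}\t0\t{f.strand}\n")


def read_fragments_sam(path, reference: str | None = None,
                       min_mapq: int = 0) -> list[Fragment]:
    """Extract proper-pair, sense-strand fragments from a SAM/BAM file.

    Each properly paired read-1 alignment on the forward strand defines one
    fragment spanning the template length from its start.
    """
    import pysam

    frags = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if (rec.is_unmapped or not rec.is_proper_pair or rec.is_read2
                    or rec.is_reverse or rec.mapping_quality < min_mapq):
                continue
            if reference is not None and rec.reference_name != reference:
                continue
            tlen = abs(rec.template_length)
            if tlen == 0:
                continue
            frags.append(Fragment(rec.reference_name, rec.reference_start,
                                  rec.reference_start + tlen, "+", True))
    return frags


def read_region_map(path) -> PegRegionMap:
    """Load a pegRNA region map from YAML.

    Either ``lengths: {spacer: 20, scaffold: 76, ...}`` or explicit
    ``regions: [{name, start, end}, ...]`` with ``length``; optional
    ``start_tol`` / ``end_tol`` (default 3 nt each).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    st = int(doc.get("start_tol", 3))
    et = int(doc.get("end_tol", 3))
    if "lengths" in doc:
        return PegRegionMap.from_lengths(start_tol=st, end_tol=et, **doc["lengths"])
    regions = tuple((r["name"], int(r["start"]), int(r["end"]))
                    for r in doc["regions"])
    return PegRegionMap(int(doc["length"]), regions, st, et)
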