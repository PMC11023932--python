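# Methods

This note documents the models, conventions and numerical choices behind
each pegquant pipeline, what the synthetic generators do and do not
emulate, and the known limitations.

## Target-site model

All coordinates are 0-based, half-open, on the + strand of the amplicon.
The protospacer is located by exact spacer + IUPAC-PAM search over both
strands; zero or multiple hits are errors (amplicons are desk-scale, so
the search is exhaustive). The Cas9 nick falls 3 nt 5′ of the PAM on the
protospacer strand: cut coordinate `c` means the nicked strand is cleaved
between + positions `c − 1` and `c` (`c = pam_start − 3` on +,
`c = pam_end + 3` on −). Edit positions are 1-based distances 3′ of the
nick **on the nicked strand**; for − strand hits position +k maps to
+ coordinate `c − k` and edit alleles are reverse-complemented. The
intended-edit ("HDR") allele is built by applying the edit to the
reference; a mismatch between the declared reference allele and the
amplicon is a hard error rather than a warning.

The quantification window is `[c − w, c + w)` with default half-width
w = 10 nt, clipped to the amplicon and expanded, if necessary, to contain
the intended-edit footprint. On the edited allele the window's right edge
shifts by the edit's length change, so "indel inside the window" means the
same region on either allele. Per-edit window sizes are an explicit
parameter; the default stands in when no per-design value is supplied.

## Alignment and read classification

Reads passing the quality filter (mean Phred ≥ 30 by default; per-base
masking is deliberately not implemented) are globally aligned to both
alleles with affine gaps: match +5, mismatch −4, gap open −20, gap extend
−2, where a gap run of length L costs `open + (L−1)·extend`. N never
matches anything. The read is assigned to the higher-scoring allele; ties
go to the reference, which can only deflate, never inflate, the
intended-edit frequency (configurable). Reads whose best alignment
identity (matches / alignment columns) falls below 0.60 are unaligned and
excluded from the denominator.

Indel placement inside an alignment is ambiguous (a gap in a homopolymer
can sit at several equivalent positions), so "read contains a window
indel" is defined **path-independently**: a read is indel-containing iff
*no* optimal-score alignment avoids insertions/deletions inside the
window. Operationally the aligner computes the optimal score and the best
score under a constrained DP in which deletions consuming a window
position and insertions whose left anchor (the reference index 5′ of the
gap, half-open convention) lies in the window are forbidden; equality
means an indel-free-in-window optimal alignment exists. Substitution-only
differences never count as indels. The DP kernels are numba-jitted;
reads equal in length to an allele with ≤ 4 mismatches take a gapless
fast path (provably optimal under this scoring, since a gapped
alternative costs at least 45 while 4 mismatches cost 36).

The test suite checks the score kernel against Biopython's
`PairwiseAligner` and the classification against a pure-Python oracle
that enumerates optimal-path edges backwards — two independent routes to
the same semantics.

Frequencies are exact rationals internally (`Fraction`), so the partition
identities (total intended = without + with indels; total indels = with
intended + without) hold exactly; the float properties are the correctly
rounded values. Reads are single-end; paired amplicon reads must be
merged upstream.

## Off-target flap walk

The 3′ DNA flap is the reverse complement of the RT template (U pairs as
A), oriented 5′→3′ along the nicked strand from the nick. Walking the
flap along the off-target amplicon, the first mismatch defines the
diagnostic site; a flap that never mismatches (or an amplicon that ends
first) is an error — the site is not quantifiable by this method. The
diagnostic site depends only on amplicon, nick and flap, never on reads.

Reads are aligned in single-allele mode against the off-target reference
with a window of half-width 10 at the off-target nick. Window-indel reads
are counted once, in `n_indel`, and excluded from base calling (reads
that are both converted and indel-containing count as indel — nucleotide
frequencies are conventionally tabulated over indel-free reads only; the
behaviour is a documented choice since either convention is defensible).
An N at the diagnostic position never counts as converted. Off-target
loci come from experimental catalogues; no genome-wide nomination is
attempted, and the off-target protospacer hit is supplied by the caller
because off-target sites generally mismatch the spacer.

## Screen statistics

The count floor ("read count minimum of 50 per sgRNA within each
sample") is implemented as a per-sample floor — counts below 50 are
raised to 50 — which preserves the library and stabilizes log-ratios; a
`filter` mode that drops rows below the floor in both samples is provided
for sensitivity analysis, since flooring versus filtering is an open
reading. No further pseudocount exists: flooring makes zeros impossible.

Phenotype: `r = log2((count_pos/total_pos)/(count_neg/total_neg))`
centred on the non-targeting median (a second centring pass guarantees
the NT median is exactly 0 even for even NT counts, where one pass can
leave a rounding error). Phenotypes are invariant under rescaling either
sample. Gene/TSS scores average the signed phenotypes of the k = 3
strongest sgRNAs by absolute value (all sgRNAs when fewer than k); genes
with multiple TSSs also report the largest-magnitude TSS score as the
gene-level score — the collapse rule is this package's convention, as
per-TSS scores are the primary object.

Pseudogenes are random groups of 5 non-targeting sgRNAs: disjoint groups
(floor(n_nt/5) of them) by default, or resampling with replacement when a
deeper null is needed. The empirical p-value uses the plus-one rule,
`p = (1 + #{|pseudo| ≥ |gene|}) / (1 + P)`, two-sided on magnitude,
followed by Benjamini–Hochberg across genes; hits are FDR ≤ 0.01. Because
p cannot go below `1/(P+1)`, calling hits at strict thresholds over many
genes requires a deep null (e.g. P = 200,000 resampled pseudogenes for
FDR ≤ 0.01 over ~19,000 genes — with 20 genes tied at the floor, BH gives
`(1/(P+1)) · n_genes / 20 ≈ 0.005`). The published analysis calls hits
with an external hierarchical mixture model; this package implements the
pseudogene empirical FDR as its own testable stage and exports the sgRNA
phenotype table (sgrna_id, gene, phenotype, non-targeting flag) for the
external tool. Hit counts from the two methods are not expected to
coincide.

A calibration subtlety: when checking that ~5% of null genes reach
p ≤ 0.05, every gene is compared against the *same* pseudogene set, so
the observed fraction has variance `p(1−p)(1/n_genes + 1/P)` — the
shared-threshold term `1/P` dominates the naive binomial term. The
acceptance check uses this standard error with disjoint pseudogenes
(where the independence behind the formula holds); the naive binomial
band would be incorrectly tight for any finite pseudogene set. The
companion uniformity check (KS statistic of the empirical p-values)
instead uses a deep resampled null, because with P disjoint groups the
null's own sampling error contributes ~1/√P to the KS statistic —
≈ 0.037 at P = 750 — which would swamp a 0.05 bound regardless of how
well calibrated the procedure is.

## Fragment integrity

Eligible fragments are proper-pair, sense-strand intervals on the pegRNA
reference. Bins, with start/end tolerances (default 3 nt each):
cis-active iff `start ≤ start_tol` and `end ≥ L − end_tol`; trans-active
iff the 3′ end is intact but the 5′ end is not; inactive otherwise. The
exact interval definitions in the original supplementary material are
not reproduced here; this rule encodes the functional reading (a
cis-active molecule needs both an intact spacer 5′ end and an intact 3′
extension to direct editing in cis) and every tolerance is configurable,
so alternative readings are one config change away. Increasing the end
tolerance can only grow the cis+trans count (monotone by construction).

Annotation assignment for overlapping features minimizes
`|Δstart| + |Δend|` over overlapping annotations — the sum of endpoint
distances is the package's reading of "closest start and end"; ties break
to the shorter annotation, then lexicographically, making assignment
order-independent. Coverage uses a difference array, so coverage summed
over positions equals summed fragment lengths exactly. The 3′-intact
fraction is the proportion of fragments with `end ≥ L − tol`.
Genome-side biotype quantification of non-pegRNA fragments is out of
scope; the assignment operator applies to any annotation set supplied.

## Synthetic data

`sim_amplicon_reads` draws each read's class from the programmed mixture
(defaults 0.25/0.05/0.10/0.60 for intended-clean / intended+indel /
indel-only / unedited), emits the corresponding allele, applies one
window indel for indel classes (length uniform 1–5 nt, deletions twice
as likely as insertions, placed uniformly in the window — matching where
nick-to-nick indels concentrate), then i.i.d. substitution errors
(default 0.1%, the scale of modern short-read platforms). Two generator
contracts keep the truth table honest: an indel may not overlap the
intended-edit footprint of an intended+indel read (otherwise the edit
would no longer be present and the programmed class would be a lie), and
an indel's shift-equivalence range — the positions where an optimal
alignment may equivalently place it, computed from the repeat structure
of the sequence — must lie inside the window (otherwise it would not be
a window indel under optimal alignment). Qualities are constant Phred 37
by default; `random_quals` draws per-read levels spanning the q30 filter
so the quality path is exercised. Not modelled: quality- or
context-dependent errors, homopolymer artefacts, PCR duplicates,
paired-end structure.

`sim_screen` emulates a genome-scale CRISPRi library: 18,905 genes × 5
sgRNAs plus 3,751 non-targeting controls (≈4% of the library; odd by
choice, so the NT median is an actual library member and centring is
exact). Library abundance is log-normal with σ = 0.5 (normalized to mean
1), sampling is negative-binomial with mean `depth × abundance` (default
depth 500×) and size parameter 30 — moderate overdispersion typical of a
well-executed sorted screen (≈18% extra CV at depth 500); `size = ∞`
gives the Poisson limit. Planted regulators multiply the marker-positive
expectation by `2^effect` for the chosen number of active sgRNAs
(default 3 of 5, reflecting that not all sgRNAs of a real hit knock down
effectively). Real screens add noise this generator omits: infection
and sorting bottlenecks, chromatin-position effects, sgRNA efficacy
heterogeneity beyond the active/inactive split, and replicate-level
technical variation — recovery results on synthetic screens are
best-case statements about the statistics, not about any particular
experiment.

`sim_fragments` draws either from programmed bin proportions (default
0.6/0.1/0.3) with endpoints uniform within each bin's constraints, or
from a truncated-geometric 5′/3′ truncation model (per-base survival
1 − p, default p = 0.02 per end) with inverse-CDF sampling; the
truncated-geometric mean used to validate it is computed by direct
summation. The default 122-nt anatomy is a 20-nt spacer, 76-nt scaffold,
13-nt RT template and 13-nt PBS.

Every generator takes an explicit seed, uses one `numpy` Generator per
call (no global state), is byte-reproducible under the same seed, and
emits a truth table sufficient to score recovery without re-deriving it.

## Problem sizes and determinism

The test suite runs the mixture-recovery study at 100 seeds × 10,000
reads, screen recovery at 20 genome-scale seeds, and the null
calibration at 20,000 genes — sizes chosen so the statistical claims are
sharp while the whole suite stays a coffee-break run on one core. The
acceptance script runs one seed of each pipeline at the same scales. All
stochastic tests are seeded; hypothesis-based property tests use fixed
profiles.

## Known limitations

* The alignment engine reimplements only the subset needed for outcome
  classification — no allele-frequency plots, no batch reports, no base
  editing mode, no paired-end merging, no genome-scale alignment.
* The denominator convention (reads aligned to either allele at ≥60%
  identity) is pinned here; external quantifiers may treat
  ambiguous-alignment edge cases differently.
* Empirical FDR and the external mixture model answer related but not
  identical questions; use the export when mixture-model hit calling is
  required.
* Differential pegRNA abundance between conditions belongs to dedicated
  count-model tools and is out of scope; this package stops at per-sample
  binning, coverage and summary fractions.
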