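"""Quantify prime-editing outcomes at a target amplicon.

Builds a random editing locus (amplicon + matched pegRNA design with a
2-bp substitution at +7), simulates 2,000 sequencing reads from a known
outcome mixture, and runs the read classifier.  The printed frequencies
are proportions of reads that aligned to either allele: "intended edit"
is editing without indels near the nick, "indels" counts every read with
an insertion/deletion inside the quantification window.
"""

from pegquant.quantify import quantify_reads
from pegquant.simulate import OutcomeMixture, random_editing_locus, sim_amplicon_reads

amplicon, design = random_editing_locus(length=200, seed=7)
edit = design.intended_edit
print(f"locus: {len(amplicon)} bp, spacer {design.spacer}")
print(f"intended edit: +{edit.position_rel_nick} "
      f"{edit.ref_allele}-to-{edit.alt_allele} substitution\n")

mixture = OutcomeMixture(proportions=(0.25, 0.05, 0.10, 0.60), error_rate=0.001)
reads, truth = sim_amplicon_reads(amplicon, design, mixture, n=2000, seed=1)

result = quantify_reads(reads, amplicon, design)
t = result.tally
print(f"aligned reads: {t.n_aligned} / {t.n_total}")
print(f"window: [{result.ref_window.start}, {result.ref_window.end}) "
      f"around nick at {result.cut}")
print(f"intended edit (no indels):   {100 * t.f_intended_wo_indel:6.2f} %  "
      f"(programmed 25)")
print(f"intended edit with indels:   {100 * t.f_intended_w_indel:6.2f} %  "
      f"(programmed 5)")
print(f"total intended edit:         {100 * t.f_total_intended:6.2f} %")
print(f"total indels:                {100 * t.f_total_indels:6.2f} %  "
      f"(programmed 15)")
print(f"indels without intended:     {100 * t.f_indels_wo_intended:6.2f} %  "
      f"(programmed 10)")
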