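import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pegquant.design import QuantWindow, build_edited_allele, edit_windows
from pegquant.quantify import (EmptyRead, OutcomeTally, ReadClass, ReadRecord,
                               ZeroAligned, align_and_assign, classify_read,
                               passes_quality, quantify_reads, tally)

from _oracle import classify_oracle


class TestQuality:
    def test_mean_at_threshold_passes(self):
        read = ReadRecord("r", "ACGT", (30, 30, 30, 30))
        assert passes_quality(read, 30)

    def test_mean_below_threshold_fails(self):
        read = ReadRecord("r", "ACGTACGTAC", (29,) * 9 + (38,))
        assert read.mean_quality() < 30
        assert not passes_quality(read, 30)

    def test_empty_read_raises(self):
        with pytest.raises(EmptyRead):
            passes_quality(ReadRecord("r", "", ()), 30)

    def test_qual_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ReadRecord("r", "ACGT", (30, 30))


@pytest.fixture(scope="module")
def alleles(plus_amplicon, sub_design):
    ref = plus_amplicon.sequence
    hdr = build_edited_allele(plus_amplicon, 37, "+", sub_design.intended_edit)
    ref_win, hdr_win = edit_windows(plus_amplicon, 37, "+",
                                    sub_design.intended_edit, 10)
    return ref, hdr, ref_win, hdr_win


class TestAlignAndAssign:
    def test_read_equal_to_hdr_assigned_hdr(self, alleles):
        ref, hdr, ref_win, hdr_win = alleles
        asn = align_and_assign(hdr, ref, hdr, ref_win, hdr_win)
        assert asn.assigned == "HDR" and asn.identity == 1.0

    def test_read_equal_to_ref_assigned_ref(self, alleles):
        ref, hdr, ref_win, hdr_win = alleles
        asn = align_and_assign(ref, ref, hdr, ref_win, hdr_win)
        assert asn.assigned == "REF" and asn.identity == 1.0

    def test_unrelated_read_unassigned(self, alleles):
        ref, hdr, ref_win, hdr_win = alleles
        rng = np.random.default_rng(123)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, size=50))
        asn = align_and_assign(junk, ref, hdr, ref_win, hdr_win)
        assert asn.identity < 0.60
        assert asn.assigned is None
        assert classify_read(asn) is ReadClass.UNALIGNED

    def test_tie_goes_to_reference(self, alleles):
        ref, hdr, ref_win, hdr_win = alleles
        # a read equidistant from both alleles: delete the edited position
        read = ref[:41] + ref[42:]
        asn = align_and_assign(read, ref, hdr, ref_win, hdr_win)
        assert asn.assigned == "REF"


class TestClassifyRead:
    def test_exact_edited_read_is_hdr_clean(self, alleles):
        ref, hdr, ref_win, hdr_win = alleles
        asn = align_and_assign(hdr, ref, hdr, ref_win, hdr_win)
        assert classify_read(asn) is ReadClass.HDR_CLEAN

    def test_window_deletion_on_reference_is_ref_indel(self, alleles):
        ref, hdr, ref_win, hdr_win = alleles
        read = ref[:30] + ref[32:]  # 2-bp deletion inside [27,47)
        asn = align_and_assign(read, ref, hdr, ref_win, hdr_win)
        assert classify_read(asn) is ReadClass.REF_INDEL

    def test_indel_outside_window_is_clean(self, alleles):
        ref, hdr, ref_win, hdr_win = alleles
        pos = ref_win.end + 10  # insertion far 3' of the window
        read = ref[:pos] + "T" + ref[pos:]
        asn = align_and_assign(read, ref, hdr, ref_win, hdr_win)
        assert classify_read(asn) is ReadClass.REF_CLEAN

    def test_substitutions_never_count_as_indels(self, alleles):
        ref, hdr, ref_win, hdr_win = alleles
        read = list(ref)
        read[30] = "A" if ref[30] != "A" else "C"  # mismatch inside window
        asn = align_and_assign("".join(read), ref, hdr, ref_win, hdr_win)
        assert classify_read(asn) is ReadClass.REF_CLEAN

    def test_edited_read_with_window_deletion_is_hdr_indel(self, alleles):
        ref, hdr, ref_win, hdr_win = alleles
        read = hdr[:30] + hdr[32:]
        asn = align_and_assign(read, ref, hdr, ref_win, hdr_win)
        assert classify_read(asn) is ReadClass.HDR_INDEL

    def test_shiftable_boundary_deletion_uses_optimal_placement(self):
        # deletion of one T from a TTTT run straddling the window edge can
        # be realigned outside the window, so the read is clean
        ref = "ACGACGACG" + "TTTT" + "ACGACGACGACG"
        read = ref[:10] + ref[11:]  # delete a T at index 10
        win = QuantWindow(5, 3, 2, 11)  # span [2,11): run extends to 13
        asn = align_and_assign(read, ref, ref, win, win)
        assert classify_read(asn, win) is ReadClass.REF_CLEAN


class TestTally:
    def test_worked_example(self):
        classes = ([ReadClass.HDR_CLEAN] * 25 + [ReadClass.HDR_INDEL] * 5
                   + [ReadClass.REF_INDEL] * 10 + [ReadClass.REF_CLEAN] * 60)
        t = tally(classes)
        assert t.f_intended_wo_indel == 0.25
        assert t.f_total_intended == 0.30
        assert t.f_total_indels == 0.15
        assert t.f_indels_wo_intended == 0.10

    def test_all_reference_reads_give_zero_frequencies(self):
        t = tally([ReadClass.REF_CLEAN] * 7)
        assert (t.f_intended_wo_indel, t.f_total_intended, t.f_total_indels) == (0, 0, 0)

    def test_zero_aligned_raises(self):
        t = tally([ReadClass.UNALIGNED, ReadClass.DISCARDED_QUALITY])
        assert t.n_aligned == 0
        with pytest.raises(ZeroAligned):
            t.f_total_indels

    @given(counts=st.tuples(*[st.integers(0, 10_000)] * 6))
    @settings(max_examples=300, deadline=None)
    def test_partition_and_identities_hold_exactly(self, counts):
        """Class counts partition reads; frequency identities are exact."""
        classes = dict(zip(ReadClass, counts))
        if sum(classes[c] for c in (ReadClass.HDR_CLEAN, ReadClass.HDR_INDEL,
                                    ReadClass.REF_INDEL, ReadClass.REF_CLEAN)) == 0:
            return
        t = OutcomeTally(classes)
        assert t.n_total == sum(counts)
        f = t.exact_frequencies()
        assert f["f_total_intended"] == f["f_intended_wo_indel"] + f["f_intended_w_indel"]
        assert f["f_total_indels"] == f["f_intended_w_indel"] + f["f_indels_wo_intended"]
        for v in (t.f_intended_wo_indel, t.f_intended_w_indel, t.f_total_intended,
                  t.f_total_indels, t.f_indels_wo_intended):
            assert 0.0 <= v <= 1.0

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(2)
        classes = list(rng.choice(list(ReadClass), size=200))
        t1, t2 = tally(classes), tally(classes[::-1])
        assert t1.counts == t2.counts


class TestPipeline:
    def test_error_free_round_trip(self, plus_amplicon, sub_design):
        """Verbatim allele copies classify 100% clean."""
        hdr = build_edited_allele(plus_amplicon, 37, "+", sub_design.intended_edit)
        reads = ([ReadRecord(f"h{i}", hdr, (37,) * len(hdr)) for i in range(20)]
                 + [ReadRecord(f"r{i}", plus_amplicon.sequence,
                               (37,) * len(plus_amplicon)) for i in range(30)])
        res = quantify_reads(reads, plus_amplicon, sub_design)
        assert res.tally.counts[ReadClass.HDR_CLEAN] == 20
        assert res.tally.counts[ReadClass.REF_CLEAN] == 30

    def test_low_quality_reads_are_discarded(self, plus_amplicon, sub_design):
        seq = plus_amplicon.sequence
        reads = [ReadRecord("bad", seq, (10,) * len(seq)),
                 ReadRecord("good", seq, (37,) * len(seq))]
        res = quantify_reads(reads, plus_amplicon, sub_design)
        assert res.tally.counts[ReadClass.DISCARDED_QUALITY] == 1
        assert res.tally.n_aligned == 1


def _mutate(rng, seq):
    """Apply one random event: substitution, insertion <=3, or deletion <=3."""
    seq = list(seq)
    op = int(rng.integers(0, 3))
    pos = int(rng.integers(0, len(seq)))
    if op == 0:
        seq[pos] = "ACGT"[int(rng.integers(0, 4))]
    elif op == 1:
        ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=int(rng.integers(1, 4))))
        seq.insert(pos, ins)
    else:
        del seq[pos:pos + int(rng.integers(1, 4))]
    return "".join(seq)


def test_classification_agrees_with_bruteforce_oracle():
    """On short amplicons with <=2 events, classification matches the
    enumerate-all-optimal-alignments oracle."""
    rng = np.random.default_rng(2024)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    n_checked = 0
    for _ in range(150):
        n = int(rng.integers(40, 61))
        ref = bytes(rng.choice(bases, size=n)).decode()
        epos = int(rng.integers(10, n - 10))
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref[epos]:
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref[epos]]
        hdr = ref[:epos] + alt + ref[epos + 1:]
        center = epos + int(rng.integers(-3, 4))
        win = QuantWindow(center, 6).clipped(n)
        win = win.expanded_to(epos, epos + 1).clipped(n)
        src = ref if rng.random() < 0.5 else hdr
        read = src
        for _ in range(int(rng.integers(0, 3))):
            read = _mutate(rng, read)
        if not read:
            continue
        asn = align_and_assign(read, ref, hdr, win, win)
        if asn.assigned is None:
            continue
        got = classify_read(asn).value
        expected = classify_oracle(read, ref, hdr, win.span, win.span)
        assert got == expected
        n_checked += 1
    assert n_checked >= 100
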