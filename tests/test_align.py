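"""Affine-gap global alignment and read classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hdrquant as hq
from hdrquant.align import Alignment, AlignmentOp

from conftest import (
    enumerated_best_score,
    make_donor,
    make_locus,
    oracle_score,
    random_sequence_pairs,
)

SC = hq.Scoring()  # +2 / -3 / -5 / -2
dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestGlobalAlign:
    def test_identity_alignment_has_no_gaps(self, locus):
        aln = hq.global_align(locus.reference, locus.reference)
        assert aln.aligned_read == aln.aligned_ref == locus.reference
        assert aln.score == 2 * len(locus.reference)
        assert [op.kind for op in aln.ops] == ["match"]

    def test_one_base_deletion_example(self):
        # brute-force enumeration over all global alignments of these
        # sequences confirms the optimum: 4 matches + 1-bp gap = 8 - 7 = 1
        aln = hq.global_align("ACGT", "ACGGT", SC)
        assert aln.score == 1 == enumerated_best_score("ACGT", "ACGGT", SC)
        dels = [op for op in aln.ops if op.kind == "deletion"]
        assert len(dels) == 1 and dels[0].length == 1
        assert not any(op.kind == "insertion" for op in aln.ops)

    def test_single_mismatch_score(self, locus):
        read = "T" + locus.reference[1:] if locus.reference[0] != "T" \
            else "A" + locus.reference[1:]
        aln = hq.global_align(read, locus.reference)
        L = len(locus.reference)
        assert aln.score == (L - 1) * SC.match + SC.mismatch

    def test_gap_length_cost_is_open_plus_extend_per_base(self):
        # 3-bp insertion into otherwise identical sequences
        ref = "ACGTACGTACGTACGTACGT"
        read = ref[:10] + "TTT" + ref[10:]
        aln = hq.global_align(read, ref, SC)
        assert aln.score == len(ref) * SC.match + SC.gap_open + 3 * SC.gap_extend

    def test_gap_removal_reproduces_inputs_and_ops_tile(self):
        read, ref = "GGATCCGTA", "GGTCCCGTAA"
        aln = hq.global_align(read, ref, SC)
        assert aln.read == read and aln.reference == ref
        n_read = sum(op.length for op in aln.ops if op.kind != "deletion")
        n_ref = sum(op.length for op in aln.ops if op.kind != "insertion")
        assert n_read == len(read) and n_ref == len(ref)

    def test_mismatch_preferred_over_gap_pair_at_equal_score(self):
        # with these scores a substitution (-2) ties an indel pair (-1-1)
        sc = hq.Scoring(match=0, mismatch=-2, gap_open=0, gap_extend=-1)
        aln = hq.global_align("A", "T", sc)
        assert [op.kind for op in aln.ops] == ["mismatch"]

    def test_deterministic(self):
        a, b = "ACGTACGGTACCA", "ACGTACGTACGTA"
        assert hq.global_align(a, b, SC) == hq.global_align(a, b, SC)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            hq.global_align("", "ACGT")
        with pytest.raises(ValueError):
            hq.global_align("ACGT", "")

    def test_oracle_agrees_with_enumeration_on_tiny_pairs(self):
        # validates the memoized recursion against full path enumeration
        for a, b in random_sequence_pairs(40, 5, seed=99):
            assert oracle_score(a, b, SC) == enumerated_best_score(a, b, SC)

    def test_score_optimal_versus_independent_oracle(self):
        for a, b in random_sequence_pairs(120, 8, seed=17):
            assert hq.global_align(a, b, SC).score == oracle_score(a, b, SC)

    @settings(max_examples=60, derandomize=True)
    @given(a=dna, b=dna)
    def test_score_symmetric_under_sequence_swap(self, a, b):
        # deletion and insertion costs are symmetric, so swapping the
        # sequences preserves the optimal score
        assert hq.global_align(a, b, SC).score == hq.global_align(b, a, SC).score


def _mk_alignment(read: str, ref: str) -> Alignment:
    return hq.global_align(read, ref, SC)


class TestDetectWindowIndels:
    # random reference; window chosen away from long repeats
    REF = make_locus(seed=5).reference
    WINDOW = make_locus(seed=5).window

    def _nonmatching_base(self, *avoid: str) -> str:
        return next(b for b in "ACGT" if b not in avoid)

    def test_deletion_at_cut_site_detected(self):
        cut = (self.WINDOW[0] + self.WINDOW[1]) // 2
        read = self.REF[:cut] + self.REF[cut + 2:]
        hit, events = hq.detect_window_indels(_mk_alignment(read, self.REF), self.WINDOW)
        assert hit and events[0].kind == "deletion"

    def test_deletion_far_downstream_not_detected(self):
        pos = self.WINDOW[1] + 30
        read = self.REF[:pos] + self.REF[pos + 3:]
        hit, events = hq.detect_window_indels(_mk_alignment(read, self.REF), self.WINDOW)
        assert not hit and events == []

    def test_insertion_at_window_start_boundary_detected(self):
        ws = self.WINDOW[0]
        # base chosen so the insertion anchor cannot shift out of the window
        ins = self._nonmatching_base(self.REF[ws - 1], self.REF[ws])
        read = self.REF[:ws] + ins + self.REF[ws:]
        hit, _ = hq.detect_window_indels(_mk_alignment(read, self.REF), self.WINDOW)
        assert hit

    def test_insertion_at_exclusive_window_end_not_detected(self):
        we = self.WINDOW[1]
        ins = self._nonmatching_base(self.REF[we - 1], self.REF[we])
        read = self.REF[:we] + ins + self.REF[we:]
        hit, _ = hq.detect_window_indels(_mk_alignment(read, self.REF), self.WINDOW)
        assert not hit

    def test_homopolymer_deletion_counted_via_equivalent_placements(self):
        # a deletion inside the window whose optimal alignment placement can
        # slide to the start of a homopolymer run outside the window must
        # still count: all score-equivalent placements are considered
        ref = self.REF[:20] + "A" * 8 + self.REF[28:]
        window = (24, 34)
        read = ref[:25] + ref[26:]  # delete an A inside the window
        aln = _mk_alignment(read, ref)
        hit, events = hq.detect_window_indels(aln, window)
        assert hit and events[0].kind == "deletion"


class TestDetectDonorSnps:
    def test_hdr_read_matches_all_donor_positions(self, locus, donor_with_block):
        read = hq.apply_hdr(locus.reference, donor_with_block)
        calls = hq.detect_donor_snps(hq.global_align(read, locus.reference), donor_with_block)
        assert len(calls) == 3  # 1 target SNP + 2 PAM-block positions
        assert all(c.matches_donor for c in calls)

    def test_reference_read_matches_nothing(self, locus, donor_with_block):
        aln = hq.global_align(locus.reference, locus.reference)
        calls = hq.detect_donor_snps(aln, donor_with_block)
        assert not any(c.matches_donor for c in calls)
        assert all(c.observed == c.ref_allele for c in calls)

    def test_deleted_snp_position_is_undetermined(self, locus, donor):
        # constructed alignment with a 1-bp deletion exactly at the SNP
        pos = donor.target_snps[0][0]
        ref = locus.reference
        aln = Alignment(
            aligned_read=ref[:pos] + "-" + ref[pos + 1:],
            aligned_ref=ref,
            score=0,
            ops=(),
        )
        calls = hq.detect_donor_snps(aln, donor)
        assert calls[0].observed is None
        assert not calls[0].matches_donor


class TestClassifyRead:
    def test_unmodified(self, locus, donor):
        call = hq.classify_read(locus.reference, locus, donor)
        assert call.outcome == "UNMODIFIED" and not call.window_indel

    def test_hdr(self, locus, donor_with_block):
        read = hq.apply_hdr(locus.reference, donor_with_block)
        call = hq.classify_read(read, locus, donor_with_block)
        assert call.outcome == "HDR"
        assert all(c.matches_donor for c in call.snp_calls)

    def test_hdr_plus_window_insertion_counts_as_indel(self, locus, donor):
        cut = locus.cut_site
        hdr = hq.apply_hdr(locus.reference, donor)
        read = hdr[:cut] + "A" + hdr[cut:]
        call = hq.classify_read(read, locus, donor)
        assert call.outcome == "INDEL"
        assert call.window_indel

    def test_bare_donor_oligo_discarded_by_coverage_filter(self, locus, donor):
        call = hq.classify_read(donor.sequence, locus, donor)
        assert call.outcome == "DISCARDED"
        assert "span" in call.reason

    def test_pam_block_only_incorporation_is_not_hdr(self, locus, donor_with_block):
        read = list(locus.reference)
        for pos, _, alt in donor_with_block.pam_block:
            read[pos] = alt
        call = hq.classify_read("".join(read), locus, donor_with_block)
        assert call.outcome == "UNMODIFIED"
        by_target = {c.is_target: c.matches_donor for c in call.snp_calls}
        assert by_target[False] and not by_target[True]

    def test_substitution_errors_leave_read_unmodified(self, locus, donor):
        rng = np.random.default_rng(4)
        read = hq.apply_sequencing_errors(locus.reference, 0.01, rng)
        call = hq.classify_read(read, locus, donor)
        assert call.outcome == "UNMODIFIED"

    def test_indel_outside_window_leaves_read_eligible_for_hdr(self, locus, donor):
        hdr = hq.apply_hdr(locus.reference, donor)
        pos = locus.window[1] + 40
        read = hdr[:pos] + hdr[pos + 2:]
        call = hq.classify_read(read, locus, donor)
        assert call.outcome == "HDR"

    def test_empty_read_discarded_with_reason(self, locus, donor):
        call = hq.classify_read(("r0", ""), locus, donor)
        assert call.outcome == "DISCARDED"
        assert "failed" in call.reason


class TestClassifySample:
    def test_partition_every_read_gets_exactly_one_class(self, locus, donor):
        mix = hq.OutcomeMix(0.65, 0.15, 0.15, 0.05, n_reads=400, error_rate=0.001,
                            contamination_fraction=0.05, seed=21)
        sim = hq.simulate_sample(locus, donor, mix)
        calls = hq.classify_sample(sim.records, locus, donor)
        assert len(calls) == mix.n_reads
        assert all(c.outcome in hq.align.OUTCOMES for c in calls)

    def test_noise_free_closure_recovers_every_truth_label(self, locus, donor_with_block):
        label_map = {"unmodified": "UNMODIFIED", "hdr": "HDR", "indel": "INDEL",
                     "hdr_and_indel": "INDEL"}
        mix = hq.OutcomeMix(0.6, 0.2, 0.15, 0.05, n_reads=2000,
                            error_rate=0.0, seed=31)
        sim = hq.simulate_sample(locus, donor_with_block, mix)
        calls = hq.classify_sample(sim.records, locus, donor_with_block)
        for truth, call in zip(sim.truth, calls):
            assert call.outcome == label_map[truth.label], truth
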