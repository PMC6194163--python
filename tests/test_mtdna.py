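"""mtDNA calling: heteroplasmy, deletion breakpoints, copy number, triage."""

import numpy as np
import pytest

from mitotriage import (
    MtPileup,
    MtRead,
    assess_copy_number,
    call_point_variants,
    classify_mt_findings,
    detect_deletions,
    split_align_read,
)
from mitotriage.mtdna import MtDeletionCall


def pileup(pos, ref, alt, alt_depth, total):
    return MtPileup(pos, ref, {alt: alt_depth, ref: total - alt_depth})


class TestPointCalling:
    def test_heteroplasmy_is_alt_over_total(self, known_table):
        calls = call_point_variants([pileup(13513, "G", "A", 720, 1000)], known_table)
        (c,) = calls
        assert c.heteroplasmy == pytest.approx(0.72)
        assert c.known_pathogenic and c.passed_cutoff
        assert c.label == "Leigh"

    def test_two_percent_cutoff_for_known_five_for_novel(self, known_table):
        known = call_point_variants([pileup(3243, "A", "G", 30, 1000)], known_table)
        assert known[0].passed_cutoff  # 3% >= 2% (known pathogenic)
        novel = call_point_variants([pileup(5000, "A", "T", 30, 1000)], known_table)
        assert not novel[0].passed_cutoff  # 3% < 5% (not in the table)

    def test_cutoffs_inclusive(self, known_table):
        assert call_point_variants([pileup(3243, "A", "G", 20, 1000)], known_table)[0].passed_cutoff
        assert call_point_variants([pileup(5000, "A", "T", 50, 1000)], known_table)[0].passed_cutoff

    def test_no_alt_reads_yields_empty_list(self, known_table):
        assert call_point_variants([MtPileup(3243, "A", {"A": 1000})], known_table) == []

    def test_dloop_positions_excluded(self, known_table):
        with pytest.warns(UserWarning, match="D-loop"):
            calls = call_point_variants([pileup(16100, "A", "T", 500, 1000)], known_table)
        assert calls == []
        with pytest.warns(UserWarning, match="D-loop"):
            assert call_point_variants([pileup(300, "A", "T", 500, 1000)], known_table) == []

    def test_zero_depth_site_skipped_with_warning(self, known_table):
        with pytest.warns(UserWarning, match="zero depth"):
            assert call_point_variants([MtPileup(5000, "A", {})], known_table) == []

    def test_invariant_to_pileup_order(self, known_table):
        piles = [pileup(13513, "G", "A", 720, 1000), pileup(3243, "A", "G", 300, 1000)]
        assert call_point_variants(piles, known_table) == call_point_variants(
            piles[::-1], known_table
        )

    def test_homoplasmic_limit(self, known_table):
        (c,) = call_point_variants([pileup(11778, "G", "A", 1000, 1000)], known_table)
        assert c.heteroplasmy == 1.0 and c.passed_cutoff

    def test_estimator_unbiased_on_binomial_sampling(self, known_table):
        """Over 100 replicates at h=0.5 and depth 1000, the mean estimate
        stays within 3 standard errors of the truth."""
        rng = np.random.default_rng(42)
        depth, h, reps = 1000, 0.5, 100
        estimates = []
        for _ in range(reps):
            alt = int(rng.binomial(depth, h))
            (c,) = call_point_variants([pileup(11778, "G", "A", alt, depth)], known_table)
            estimates.append(c.heteroplasmy)
        se = np.sqrt(h * (1 - h) / depth) / np.sqrt(reps)
        assert abs(np.mean(estimates) - h) < 3 * se


def junction_read(reference, b5, b3, split, length=120):
    return reference[b5 - split : b5] + reference[b3 - 1 : b3 - 1 + length - split]


class TestDeletionCalling:
    @pytest.mark.parametrize(
        "b5, b3, size", [(8482, 13460, 4977), (7462, 15747, 8284), (9514, 15792, 6277)]
    )
    def test_printed_breakpoint_size_convention(self, reference, b5, b3, size):
        """A single convention, size = b3 - b5 - 1, satisfies all three
        printed breakpoint/size pairs."""
        assert MtDeletionCall(b5, b3, 10).size == size
        reads = [
            MtRead(f"j{i}", junction_read(reference, b5, b3, 40 + 7 * i, 200), None)
            for i in range(5)
        ]
        (call,) = detect_deletions(reads, reference)
        assert (call.b5, call.b3, call.size) == (b5, b3, size)
        assert call.single_or_multiple == "single"

    def test_min_support_threshold(self, reference):
        reads = [MtRead(f"j{i}", junction_read(reference, 8482, 13460, 50), None) for i in range(2)]
        assert detect_deletions(reads, reference, min_support=3) == []
        assert len(detect_deletions(reads, reference, min_support=2)) == 1

    def test_two_events_flagged_multiple(self, reference):
        reads = [
            MtRead(f"a{i}", junction_read(reference, 8482, 13460, 45 + i), None) for i in range(3)
        ] + [
            MtRead(f"b{i}", junction_read(reference, 7462, 15747, 45 + i), None) for i in range(3)
        ]
        calls = detect_deletions(reads, reference)
        assert len(calls) == 2
        assert all(c.single_or_multiple == "multiple" for c in calls)

    def test_aligned_and_contiguous_reads_ignored(self, reference):
        reads = [
            MtRead("aligned", reference[100:400], 101),
            MtRead("contiguous", reference[2000:2300], None),
        ]
        assert detect_deletions(reads, reference, min_support=1) == []

    def test_short_reads_skipped(self, reference):
        reads = [MtRead("tiny", junction_read(reference, 8482, 13460, 15, 30), None)] * 4
        assert detect_deletions(reads, reference, min_support=1) == []

    def test_invariant_to_read_order(self, reference):
        reads = [
            MtRead(f"j{i}", junction_read(reference, 9514, 15792, 40 + 11 * i, 180), None)
            for i in range(4)
        ]
        assert detect_deletions(reads, reference) == detect_deletions(reads[::-1], reference)

    def test_bad_reference_length_rejected(self):
        with pytest.raises(ValueError, match="reference length"):
            detect_deletions([], "ACGT" * 10)


def brute_force_junctions(read, reference):
    """Oracle: every (b5, b3) whose junction sequence contains the read
    spanning the junction, on a toy linear reference."""
    n = len(reference)
    hits = set()
    for b5 in range(1, n):
        for b3 in range(b5 + 2, n + 1):  # at least one deleted base
            junction_seq = reference[:b5] + reference[b3 - 1 :]
            start = junction_seq.find(read)
            while start != -1:
                if start < b5 and start + len(read) > b5:
                    hits.add((b5, b3))
                start = junction_seq.find(read, start + 1)
    return hits


class TestSplitAlignmentOracle:
    """Breakpoint placement equals exhaustive junction enumeration on toy
    references; repeat-shifted representations resolve leftmost."""

    @pytest.mark.parametrize("trial", range(15))
    def test_matches_brute_force_on_random_toys(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(80, 200))
        ref = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        b5 = int(rng.integers(28, n - 45))
        b3 = int(rng.integers(b5 + 5, n - 29))
        read_len = 40
        split = int(rng.integers(10, read_len - 10))
        read = ref[b5 - split : b5] + ref[b3 - 1 : b3 - 1 + read_len - split]
        assert len(read) == read_len
        expected = brute_force_junctions(read, ref)
        got = split_align_read(read, ref + "N" * (16569 - n), anchor=8)
        # the caller works on a padded reference; junction must be the
        # leftmost of the oracle's equivalence class
        if not expected:
            assert got is None
        else:
            assert got == min(expected)

    def test_repeat_flanked_junction_reports_leftmost(self):
        rng = np.random.default_rng(99)
        core = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 150)])
        repeat = "TTAACC"
        # place the same 6-mer before b5 and before b3 so the junction is
        # ambiguous across 6 positions
        ref = core[:40] + repeat + core[40:100] + repeat + core[100:]
        b5 = 40 + len(repeat)  # 1-based end of first repeat copy
        b3_first = 100 + 2 * len(repeat) + 1  # first base after second repeat copy
        read = ref[b5 - 20 : b5] + ref[b3_first - 1 : b3_first + 19]
        expected = brute_force_junctions(read, ref)
        assert len(expected) >= len(repeat) + 1  # ambiguity class
        got = split_align_read(read, ref + "N" * (16569 - len(ref)), anchor=8)
        assert got == min(expected)

    def test_merges_repeat_shifted_reads_into_one_event(self, reference):
        # reads sampled at different offsets over the same junction collapse
        # to a single supported event
        reads = [
            MtRead(f"j{i}", junction_read(reference, 8482, 13460, 30 + 13 * i, 160), None)
            for i in range(6)
        ]
        calls = detect_deletions(reads, reference)
        assert len(calls) == 1
        assert calls[0].supporting_reads == 6


class TestCopyNumber:
    def test_depleted_at_twenty_percent(self):
        res = assess_copy_number(0.2, [1.0, 1.0, 1.0])
        assert res.percent_of_control == pytest.approx(20.0)
        assert res.depleted

    def test_identity_and_mean_normalisation(self):
        assert assess_copy_number(1.0, [1.0]).percent_of_control == pytest.approx(100.0)
        assert not assess_copy_number(1.0, [1.0]).depleted
        res = assess_copy_number(2.0, [1.0, 3.0])
        assert res.percent_of_control == pytest.approx(100.0)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="control"):
            assess_copy_number(1.0, [])
        with pytest.raises(ValueError, match="positive"):
            assess_copy_number(-1.0, [1.0])


class TestTriage:
    def test_passing_known_point_solves(self, known_table):
        calls = call_point_variants([pileup(11778, "G", "A", 1000, 1000)], known_table)
        assert classify_mt_findings(calls, []).outcome == "solved_point"

    def test_single_deletion_solves(self):
        dels = [MtDeletionCall(8482, 13460, 10)]
        assert classify_mt_findings([], dels).outcome == "solved_single_deletion"

    def test_multiple_deletions_escalate(self):
        dels = [
            MtDeletionCall(8482, 13460, 10, "multiple"),
            MtDeletionCall(7462, 15747, 8, "multiple"),
        ]
        assert classify_mt_findings([], dels).outcome == "escalate_to_wes"

    def test_depletion_escalates(self):
        cn = assess_copy_number(0.2, [1.0])
        assert classify_mt_findings([], [], cn).outcome == "escalate_to_wes"

    def test_nothing_found_is_negative(self):
        cn = assess_copy_number(1.0, [1.0])
        assert classify_mt_findings([], [], cn).outcome == "negative"

    def test_suppressed_low_level_novel_variant_does_not_solve(self, known_table):
        calls = call_point_variants([pileup(5000, "A", "T", 30, 1000)], known_table)
        assert classify_mt_findings(calls, []).outcome == "negative"
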