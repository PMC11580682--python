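import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tandemhmm.model import ModelParams, encode_sequence
from tandemhmm.decode import SubRepeat, traceback, viterbi_fill, extract_regions
from tandemhmm.split import (
    PSEUDOCOUNT, canonical_pattern, consensus_unit, find_peaks, jsd,
    merge_rotation_equivalent, normalize_profile, scan_splits, split_region,
)

units = st.text(alphabet="ACGT", min_size=1, max_size=8)


class TestCanonicalPattern:
    @pytest.mark.parametrize("rot", ["GGTT", "GTTG", "TTGG", "TGGT"])
    def test_all_rotations_name_ggtt(self, rot):
        assert canonical_pattern(rot) == "GGTT"

    def test_already_minimal(self):
        assert canonical_pattern("AAC") == "AAC"

    def test_dinucleotide(self):
        assert canonical_pattern("TA") == "AT"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            canonical_pattern("")

    @given(unit=units, shift=st.integers(0, 7))
    @settings(max_examples=100, deadline=None)
    def test_rotation_invariant_and_minimal(self, unit, shift):
        shift %= len(unit)
        rotated = unit[shift:] + unit[:shift]
        expected = min(unit[i:] + unit[:i] for i in range(len(unit)))
        assert canonical_pattern(rotated) == expected


class TestJsd:
    def test_zero_on_identical(self, rng):
        L = rng.random((4, 4))
        assert jsd(L, L) == 0.0

    def test_symmetric(self, rng):
        for _ in range(100):
            L = rng.random((3, 4))
            R = rng.random((3, 4))
            assert jsd(L, R) == pytest.approx(jsd(R, L), abs=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(50):
            assert jsd(rng.random((2, 4)), rng.random((2, 4))) >= 0.0

    def test_matches_direct_formula_single_row(self):
        """Independent one-line evaluation of the printed divergence."""
        L = np.array([[1.0, 0, 0, 0]])
        R = np.array([[0, 1.0, 0, 0]])
        eps = PSEUDOCOUNT
        l = (L + eps) / (L + eps).sum()
        r = (R + eps) / (R + eps).sum()
        expected = -0.5 * float(np.sum(l * np.log2(r / l) + r * np.log2(l / r)))
        assert jsd(L, R) == pytest.approx(expected, abs=1e-12)
        assert expected > 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jsd(np.ones((2, 4)), np.ones((3, 4)))

    def test_normalized_rows_sum_to_one(self, rng):
        P = normalize_profile(rng.integers(0, 20, (5, 4)).astype(float))
        assert np.allclose(P.sum(axis=1), 1.0)


class TestProfileIndices:
    def test_insertion_worked_example(self):
        """'CATCATCAgTCATCAT': indices 1 2 3 1 2 3 1 2 * 3 1 2 3 1 2 3."""
        params = ModelParams(max_period=5, n_insert=2, n_delete=2,
                             repeat_entry=0.05, indel_open=0.05)
        codes = encode_sequence("CATCATCAGTCATCAT" + "CATCAT")
        path = traceback(viterbi_fill(codes, params))
        regions = extract_regions(path, codes, params)
        assert len(regions) == 1
        track = regions[0].profile_indices[:16]
        assert list(track) == [1, 2, 3, 1, 2, 3, 1, 2, 0, 3, 1, 2, 3, 1, 2, 3]

    def test_pure_cycling_without_indels(self):
        params = ModelParams(max_period=3, n_insert=0, n_delete=0)
        codes = encode_sequence("ACACACACAC")
        regions = extract_regions(traceback(viterbi_fill(codes, params)),
                                  codes, params)
        assert list(regions[0].profile_indices) == [1, 2] * 5

    def test_deletion_skips_one_index(self):
        params = ModelParams(max_period=5, n_insert=2, n_delete=2,
                             repeat_entry=0.05, indel_open=0.05)
        codes = encode_sequence("AACGAACGAACGAACG" + "AAC" + "AACGAACG")
        path = traceback(viterbi_fill(codes, params))
        assert len(path.del_events) == 1
        regions = extract_regions(path, codes, params)
        track = list(regions[0].profile_indices)
        # indices cycle 1..4 but skip exactly one pattern position at the
        # deletion: ... 1 2 3 [4 skipped] 1 2 3 4 ...
        assert track[16:23] == [1, 2, 3, 1, 2, 3, 4]


class TestScanSplits:
    def test_homogeneous_repeat_has_no_splits(self):
        codes = encode_sequence("AC" * 100)
        track = (np.arange(200) % 2 + 1).astype(np.int32)
        assert scan_splits(codes, track, 2) == []

    def test_pattern_change_detected_near_junction(self):
        codes = encode_sequence("AC" * 50 + "GC" * 50)
        track = (np.arange(200) % 2 + 1).astype(np.int32)
        splits = scan_splits(codes, track, 2)
        assert len(splits) == 1
        assert abs(splits[0][0] - 100) <= 10

    def test_region_shorter_than_two_windows_reports_nothing(self):
        codes = encode_sequence("AC" * 10)
        track = (np.arange(20) % 2 + 1).astype(np.int32)
        assert scan_splits(codes, track, 2) == []

    def test_peak_plateau_resolved_leftmost(self):
        series = np.array([0.0, 5.0, 5.0, 5.0, 0.0])
        assert find_peaks(series, 3.5, 1) == [1]

    def test_min_separation_suppresses_nearby_peaks(self):
        series = np.array([0.0, 6.0, 0.0, 5.0, 0.0])
        assert find_peaks(series, 3.5, 5) == [1]
        assert find_peaks(series, 3.5, 2) == [1, 3]


class TestSubrepeats:
    def test_rotation_equivalent_neighbors_merge(self):
        subs = [SubRepeat(0, 50, "GTTG"), SubRepeat(50, 100, "GGTT")]
        merged = merge_rotation_equivalent(subs)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 100)

    def test_distinct_patterns_stay_separate(self):
        subs = [SubRepeat(0, 50, "AAAC"), SubRepeat(50, 100, "GGTT")]
        assert len(merge_rotation_equivalent(subs)) == 2

    def test_merge_runs_to_fixed_point(self):
        subs = [SubRepeat(0, 30, "ACT"), SubRepeat(30, 60, "CTA"),
                SubRepeat(60, 90, "TAC")]
        merged = merge_rotation_equivalent(subs)
        assert len(merged) == 1
        assert merged[0].pattern == "ACT"

    def test_consensus_on_perfect_repeat(self):
        codes = encode_sequence("GGTT" * 10)
        track = (np.arange(40) % 4 + 1).astype(np.int32)
        assert consensus_unit(codes, track, 4) == "GGTT"

    def test_consensus_majority_ignores_single_substitution(self):
        seq = list("AAC" * 10)
        seq[3] = "G"  # one A->G substitution
        codes = encode_sequence("".join(seq))
        track = (np.arange(30) % 3 + 1).astype(np.int32)
        assert consensus_unit(codes, track, 3) == "AAC"

    def test_consensus_tie_breaks_alphabetically(self):
        codes = encode_sequence("CA")
        track = np.array([1, 1], dtype=np.int32)
        assert consensus_unit(codes, track, 1) == "A"


class TestSplitRegionPipeline:
    def _annotate_one(self, seq, period):
        params = ModelParams(max_period=10, n_insert=0, n_delete=0)
        codes = encode_sequence(seq)
        regions = extract_regions(traceback(viterbi_fill(codes, params)),
                                  codes, params)
        assert len(regions) == 1
        return split_region(regions[0], codes), codes

    def test_two_subrepeat_sequence_split_once(self):
        region, _ = self._annotate_one("AAAC" * 60 + "GGTT" * 60, 4)
        assert len(region.subrepeats) == 2
        patterns = {s.pattern for s in region.subrepeats}
        assert patterns == {"AAAC", "GGTT"}
        assert abs(region.subrepeats[1].start - 240) <= 10

    def test_splitting_is_idempotent(self):
        region, codes = self._annotate_one("AAAC" * 60 + "GGTT" * 60, 4)
        for sub in region.subrepeats:
            seg = codes[sub.start:sub.end]
            track = region.profile_indices[sub.start - region.start:
                                           sub.end - region.start]
            assert scan_splits(seg, track, region.period) == []

    def test_subrepeats_partition_region(self):
        region, _ = self._annotate_one("AAAC" * 60 + "GGTT" * 60, 4)
        assert region.subrepeats[0].start == region.start
        assert region.subrepeats[-1].end == region.end
        for a, b in zip(region.subrepeats, region.subrepeats[1:]):
            assert a.end == b.start
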