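import numpy as np
import pytest

from tandemhmm.model import ModelParams, build_topology, encode_sequence
from tandemhmm import reference as ref
from tandemhmm.decode import (
    RepeatRegion, WindowPlan, annotate_codes, estimate_memory,
    extract_regions, merge_windows, plan_windows, score_region, traceback,
    viterbi_fill, path_emission_ratios,
)
from tandemhmm.simulate import planted_genome
from tests.conftest import random_small_params, reference_path_arrays


class TestViterbiOracle:
    def test_matches_exhaustive_enumeration(self, rng):
        """Fast decoder == brute-force path enumeration on tiny instances."""
        for _ in range(50):
            params = random_small_params(rng, k_max=2, indel_max=1)
            n = int(rng.integers(1, 11))
            codes = rng.integers(0, 4, n).astype(np.int8)
            topo = build_topology(params)
            best_score, best_path = ref.best_path_enumeration(codes, topo)
            vm = viterbi_fill(codes, params)
            path = traceback(vm)
            assert path.final_value == pytest.approx(best_score, abs=1e-9)
            V, ptr = ref.viterbi_matrix(codes, topo)
            emitted, silent = ref.traceback_matrix(V, ptr, topo)
            assert emitted == ref.emitted_states_of(best_path, topo)
            k, p, lk, dels = reference_path_arrays(emitted, silent, topo)
            assert np.array_equal(k, path.kind)
            assert np.array_equal(p, path.period)
            assert np.array_equal(lk, path.look)
            assert dels == path.del_events

    def test_aggregated_chain_update_bit_identical_to_naive(self, rng):
        """The ring-buffer J-chain update reproduces the naive per-state
        dynamic program bit for bit, including unreachable cells."""
        for _ in range(25):
            params = random_small_params(rng, k_max=3, indel_max=2)
            n = int(rng.integers(2, 13))
            codes = rng.integers(0, 5, n).astype(np.int8)  # ambiguity included
            topo = build_topology(params)
            V, _ = ref.viterbi_matrix(codes, topo)
            vm = viterbi_fill(codes, params, materialize=True)
            assert np.array_equal(V, vm.full)

    def test_background_sequence_emits_at_ratio_one(self):
        """On non-repetitive input the best path stays in the background
        state and its emission log-ratios are exactly zero: the whole path
        score is pure transition cost."""
        params = ModelParams(max_period=1, n_insert=0, n_delete=0)
        codes = encode_sequence("ACGT")
        vm = viterbi_fill(codes, params)
        path = traceback(vm)
        assert np.all(path.kind == 0)
        assert np.all(path_emission_ratios(path, codes, params) == 0.0)
        assert path.final_value == pytest.approx(
            4 * np.log(1 - params.repeat_entry), abs=1e-12)

    def test_perfect_dinucleotide_repeat_found_at_period_two(self):
        params = ModelParams(max_period=2, n_insert=0, n_delete=0)
        codes = encode_sequence("ACACACACACAC")
        path = traceback(viterbi_fill(codes, params))
        assert np.any(path.kind == 1)
        assert set(path.period[path.kind == 1]) == {2}

    def test_exact_tie_prefers_lower_period(self):
        # all-ambiguity input and decay 1: every period scores identically
        params = ModelParams(max_period=3, decay=1.0, n_insert=0, n_delete=0,
                             repeat_entry=0.9, repeat_exit=0.01)
        path = traceback(viterbi_fill(encode_sequence("NNNNNN"), params))
        assert np.all(path.period == 1)


class TestRegions:
    def test_all_background_path_yields_no_regions(self, rng):
        params = ModelParams(max_period=5, n_insert=0, n_delete=0)
        codes = rng.integers(0, 4, 200).astype(np.int8)
        path = traceback(viterbi_fill(codes, params))
        if np.all(path.kind == 0):
            assert extract_regions(path, codes, params) == []

    def test_start_adjusted_one_period_left(self):
        params = ModelParams(max_period=5, n_insert=0, n_delete=0)
        codes = encode_sequence("AACAACAACAAC")
        path = traceback(viterbi_fill(codes, params))
        regions = extract_regions(path, codes, params)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end, regions[0].period) == (0, 12, 3)

    def test_runs_below_min_unit_are_discarded(self):
        params = ModelParams(max_period=5, n_insert=0, n_delete=0)
        codes = encode_sequence("AACAACAACAAC")
        path = traceback(viterbi_fill(codes, params))
        # raw run is 9 letters (3 units); min_unit=4 must discard it
        assert extract_regions(path, codes, params, min_unit=4) == []
        assert len(extract_regions(path, codes, params, min_unit=0)) == 1

    def test_score_telescopes_to_track_difference(self, rng):
        params = ModelParams(max_period=10, n_insert=1, n_delete=1)
        codes, _ = planted_genome(20_000, 0.2, seed=3)
        vm = viterbi_fill(codes, params)
        path = traceback(vm)
        regions = extract_regions(path, codes, params)
        assert regions
        for r in regions:
            if r.end_kind == 1:
                assert score_region(r, vm) == pytest.approx(r.score, abs=1e-9)

    def test_longer_perfect_repeat_scores_higher(self):
        params = ModelParams(max_period=2, n_insert=0, n_delete=0)
        def score_of(n_units):
            codes = encode_sequence("AC" * n_units)
            path = traceback(viterbi_fill(codes, params))
            regions = extract_regions(path, codes, params)
            assert len(regions) == 1
            return regions[0].score
        assert score_of(20) > score_of(10)

    def test_null_false_coverage_small(self, rng):
        params = ModelParams(max_period=100, n_insert=2, n_delete=2)
        codes = rng.integers(0, 4, 50_000).astype(np.int8)
        regions = annotate_codes(codes, params)
        covered = sum(len(r) for r in regions)
        assert covered / len(codes) <= 0.02


class TestWindows:
    def test_small_input_gets_single_window(self):
        params = ModelParams(max_period=5, n_insert=0, n_delete=0)
        plan = plan_windows(5_000, params)
        assert plan.windows(5_000) == [(0, 5_000)]

    def test_cell_budget_formula(self):
        # ~10,000 states -> 10,000-wide windows
        params = ModelParams(max_period=44, n_insert=5, n_delete=5)
        from tandemhmm.model import state_count
        m = state_count(44, 5, 5)
        assert 10_000 <= m <= 11_000
        plan = plan_windows(10 ** 7, params)
        assert plan.window_size == max(10_000, 10 ** 8 // m)

    def test_windows_cover_and_overlap(self):
        plan = WindowPlan(1000, 100)
        wins = plan.windows(5000)
        assert wins[0][0] == 0 and wins[-1][1] == 5000
        for (a1, b1), (a2, b2) in zip(wins, wins[1:]):
            assert b1 - a2 == 100

    def test_invalid_plan_rejected(self):
        with pytest.raises(ValueError):
            WindowPlan(100, 100)

    def test_windowed_equals_single_window(self):
        params = ModelParams(max_period=20, n_insert=2, n_delete=2)
        codes, _ = planted_genome(50_000, 0.15, max_period=10, seed=11)
        single = annotate_codes(codes, params, plan=WindowPlan(50_000, 1000))
        windowed = annotate_codes(codes, params, plan=WindowPlan(20_000, 2_000))
        assert [(r.start, r.end, r.period) for r in single] == \
               [(r.start, r.end, r.period) for r in windowed]
        for a, b in zip(single, windowed):
            assert b.score == pytest.approx(a.score, rel=0.01)

    def test_merge_keeps_disjoint_regions(self):
        r1 = RepeatRegion("s", 0, 100, 2, 50.0)
        r2 = RepeatRegion("s", 500, 600, 2, 50.0)
        merged = merge_windows([((0, 1000), [r1, r2])])
        assert len(merged) == 2

    def test_merge_abutting_equal_period_adds_scores(self):
        r1 = RepeatRegion("s", 0, 100, 2, 50.0)
        r2 = RepeatRegion("s", 100, 200, 2, 40.0)
        merged = merge_windows([((0, 150), [r1]), ((50, 250), [r2])])
        assert len(merged) == 1
        assert merged[0].score == pytest.approx(90.0)
        assert (merged[0].start, merged[0].end) == (0, 200)

    def test_merge_identical_duplicate_keeps_single_score(self):
        r1 = RepeatRegion("s", 10, 110, 3, 60.0)
        r2 = RepeatRegion("s", 10, 110, 3, 60.0)
        merged = merge_windows([((0, 150), [r1]), ((50, 250), [r2])])
        assert len(merged) == 1
        assert merged[0].score == pytest.approx(60.0)


class TestMemoryEstimate:
    def test_linear_in_threads(self):
        params = ModelParams()
        plan = WindowPlan(100_000, 1000)
        fixed = estimate_memory(10 ** 6, params, plan, threads=1)
        double = estimate_memory(10 ** 6, params, plan, threads=2)
        overhead = 64 * 2 ** 20
        assert double - overhead == 2 * (fixed - overhead)

    def test_linear_in_window_size(self):
        params = ModelParams()
        one = estimate_memory(10 ** 7, params, WindowPlan(100_000, 1000), 1)
        two = estimate_memory(10 ** 7, params, WindowPlan(200_000, 1000), 1)
        overhead = 64 * 2 ** 20
        assert two - overhead == 2 * (one - overhead)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_memory(1000, ModelParams(), threads=0)
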