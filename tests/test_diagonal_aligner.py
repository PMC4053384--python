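"""Floating-band Smith-Waterman vs the full-matrix oracle; pruning admissibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import BASES, homologous_pair, mutate_subs, random_seq
from hexalign.diagonal_aligner import (
    Alignment,
    AlignerInternalError,
    ScoringParams,
    Thresholds,
    band_align,
    score_of_ops,
    score_upper_bound,
)

PARAMS = ScoringParams()


def indel_pair(rng, max_indels=3, max_size=3, n_sub_hi=10):
    sizes = [
        int(rng.integers(1, max_size + 1)) * (1 if rng.random() < 0.5 else -1)
        for _ in range(int(rng.integers(0, max_indels + 1)))
    ]
    excursion = max((abs(sum(sizes[: i + 1])) for i in range(len(sizes))), default=0)
    read, window, bracket = homologous_pair(
        rng, n_sub=int(rng.integers(0, n_sub_hi)), indel_sizes=tuple(sizes)
    )
    return read, window, bracket, excursion


class TestBasics:
    def test_perfect_match_scores_l_times_match(self, rng):
        window = random_seq(rng, 110)
        read = window[30:80]
        aln = band_align(read, window, (0, 50, 30, 80), PARAMS, w=8)
        assert aln.score == 50 * PARAMS.match
        assert aln.cigar() == "50M"
        assert aln.ops == "=" * 50

    def test_score_self_consistency(self, rng):
        for _ in range(50):
            read, window, bracket, _ = indel_pair(rng)
            aln = band_align(read, window, bracket, PARAMS, w=8)
            if aln is not None:
                assert aln.recompute_score(PARAMS) == aln.score

    def test_below_threshold_returns_none(self, rng):
        window = random_seq(rng, 160)
        read = random_seq(rng, 100)  # unrelated
        assert band_align(read, window, (0, 100, 30, 130), PARAMS, w=8) is None

    def test_bracket_outside_reference_raises(self, rng):
        window = random_seq(rng, 100)
        with pytest.raises(ValueError):
            band_align("ACGT" * 10, window, (0, 40, 90, 160), PARAMS, w=8)

    def test_memory_linear_in_band_width(self, rng):
        read, window, bracket, _ = indel_pair(rng)
        diag = {}
        band_align(read, window, bracket, PARAMS, w=8, diagnostics=diag)
        assert diag["live_cells"] <= (2 * 8 + 1) * len(read)
        assert diag["live_cells"] + diag["hole_cells"] <= (2 * 8 + 1) * len(read)


class TestOracleEquivalence:
    def test_floating_band_matches_full_sw(self, rng, sw_oracle):
        """Score equality with full-matrix SW whenever indel excursion <= w."""
        mismatches = 0
        tested = 0
        for _ in range(500):
            read, window, bracket, excursion = indel_pair(rng)
            if excursion > 8:
                continue
            aln = band_align(read, window, bracket, PARAMS, w=8)
            if aln is None:
                continue
            tested += 1
            if aln.score != sw_oracle.score(window, read):
                mismatches += 1
        assert tested > 400
        assert mismatches == 0

    def test_floating_recovers_cumulative_drift_fixed_does_not(self, rng, sw_oracle):
        """Three separated 3-base reference insertions: total diagonal drift 9
        exceeds the band half-width 4, so only the floating center keeps up."""
        read = random_seq(rng, 100)
        window = (
            read[:25] + random_seq(rng, 3) + read[25:50] + random_seq(rng, 3)
            + read[50:75] + random_seq(rng, 3) + read[75:]
        )
        bracket = (0, 100, 0, len(window))
        floating = band_align(read, window, bracket, PARAMS, w=4, float_center=True)
        fixed = band_align(read, window, bracket, PARAMS, w=4, float_center=False)
        full = sw_oracle.score(window, read)
        assert floating is not None and floating.score == full
        assert fixed is None or fixed.score < full

    def test_trajectory_reproduces_score_and_oracle_optimum(self, rng, sw_oracle):
        """The trajectory's operations reproduce the reported score under the
        additive scoring, and that score is the full-matrix optimum."""
        for _ in range(100):
            read, window, bracket, excursion = indel_pair(rng, n_sub_hi=6)
            if excursion > 8:
                continue
            aln = band_align(read, window, bracket, PARAMS, w=8)
            if aln is None:
                continue
            assert score_of_ops(aln.ops, PARAMS) == aln.score
            assert aln.score == sw_oracle.score(window, read)
            # spans are consistent with the operation counts
            assert aln.read_end - aln.read_start == aln.ops.count("=") + aln.ops.count("X") + aln.ops.count("I")
            assert aln.ref_end - aln.ref_start == aln.ops.count("=") + aln.ops.count("X") + aln.ops.count("D")


class TestPruning:
    def test_pruning_never_changes_the_result(self, rng):
        for _ in range(1000):
            read, window, bracket, _ = indel_pair(rng)
            on = band_align(read, window, bracket, PARAMS, w=8, prune=True)
            off = band_align(read, window, bracket, PARAMS, w=8, prune=False)
            assert (on is None) == (off is None)
            if on is not None:
                assert on.score == off.score
                assert on.ops == off.ops

    def test_pruning_disabled_means_zero_holes(self, rng):
        read, window, bracket, _ = indel_pair(rng)
        diag = {}
        band_align(read, window, bracket, PARAMS, w=8, prune=False, diagnostics=diag)
        assert diag["hole_cells"] == 0

    def test_pruning_produces_holes_on_weak_candidates(self, rng):
        """A seed-only candidate (random flanks) cannot reach the reporting
        threshold in its late rows, so the bound carves holes there."""
        window = random_seq(rng, 160)
        read = window[30:44] + random_seq(rng, 86)  # 14-base seed, random tail
        diag = {}
        band_align(read, window, (0, 100, 30, 130), PARAMS, w=8, prune=True, diagnostics=diag)
        assert diag["hole_cells"] > 0

    def test_upper_bound_includes_remaining_matches(self):
        assert score_upper_bound(0, 10, PARAMS, 100) == 100 + 10 * PARAMS.match
        # never below the cell's own score (the cell may be the local end)
        assert score_upper_bound(8, 0, PARAMS, 100) == 100
        bound = score_upper_bound(3, 10, PARAMS, 100)
        assert bound <= 100 + 10 * PARAMS.match
        assert bound >= 100


class TestModesAndTies:
    def test_glocal_fits_whole_read(self, rng):
        window = random_seq(rng, 160)
        read = mutate_subs(rng, window[30:130], 3)
        aln = band_align(read, window, (0, 100, 30, 130), PARAMS, w=8, mode="glocal")
        assert aln is not None
        assert aln.read_start == 0 and aln.read_end == 100

    def test_linear_gap_costs_supported(self, rng, sw_oracle):
        linear = ScoringParams(match=5, mismatch=-4, gap_open=-3, gap_extend=-3)
        from Bio import Align

        oracle = Align.PairwiseAligner()
        oracle.mode = "local"
        oracle.match_score = 5
        oracle.mismatch_score = -4
        oracle.open_gap_score = -3
        oracle.extend_gap_score = -3
        for _ in range(50):
            read, window, bracket, excursion = indel_pair(rng, n_sub_hi=5)
            if excursion > 8:
                continue
            aln = band_align(read, window, bracket, linear, w=8)
            if aln is not None:
                assert aln.score == oracle.score(window, read)

    def test_deterministic_output(self, rng):
        read, window, bracket, _ = indel_pair(rng)
        a = band_align(read, window, bracket, PARAMS, w=8)
        b = band_align(read, window, bracket, PARAMS, w=8)
        assert a == b


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=60, deadline=None)
def test_property_pruning_admissible_and_scores_consistent(seed):
    rng = np.random.default_rng(seed)
    read, window, bracket, _ = indel_pair(rng)
    on = band_align(read, window, bracket, PARAMS, w=8, prune=True)
    off = band_align(read, window, bracket, PARAMS, w=8, prune=False)
    assert (on is None) == (off is None)
    if on is not None:
        assert on.score == off.score
        assert score_of_ops(on.ops, PARAMS) == on.score
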