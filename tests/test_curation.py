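"""Curation: smoothing, threshold classification, run refinement, extraction."""

import numpy as np
import pytest

from idiomkit.curation import (
    IdrRecord,
    Label,
    PlddtTrace,
    Segment,
    SegmentationParams,
    classify_residues,
    curate_protein,
    extract_idr_records,
    refine_segments,
    segments_to_labels,
    smooth_plddt,
)
from idiomkit.fixtures import SegmentLayout, synth_protein_with_plddt

F, D, G = Label.FOLDED, Label.DISORDERED, Label.GAP


def brute_window_mean(x, window):
    half = window // 2
    out = []
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out.append(sum(x[lo:hi]) / (hi - lo))
    return np.array(out)


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        out = smooth_plddt(np.full(50, 90.0), 15)
        assert np.allclose(out, 90.0)

    def test_window_one_is_identity(self):
        x = np.array([10.0, 50.0, 99.0, 0.0])
        assert np.array_equal(smooth_plddt(x, 1), x)

    def test_step_trace_matches_bruteforce(self):
        x = np.array([100.0] * 20 + [40.0] * 20)
        assert np.allclose(smooth_plddt(x, 15), brute_window_mean(x, 15), atol=1e-12)

    @pytest.mark.parametrize("window", [3, 7, 15, 21])
    def test_random_traces_match_bruteforce(self, window):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.uniform(0, 100, rng.integers(window, 80))
            assert np.allclose(
                smooth_plddt(x, window), brute_window_mean(x, window), atol=1e-10
            )

    def test_rejects_even_window_and_empty(self):
        with pytest.raises(ValueError):
            smooth_plddt(np.array([50.0]), 4)
        with pytest.raises(ValueError):
            smooth_plddt(np.array([]), 15)


class TestClassification:
    def test_threshold_bands(self):
        labels = classify_residues(np.array([90.0, 60.0, 75.0]))
        assert labels == [F, D, G]

    def test_exact_thresholds_are_gap(self):
        assert classify_residues(np.array([80.0, 70.0])) == [G, G]

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0, 100, 300)
        got = classify_residues(s)
        for v, lab in zip(s, got):
            expected = F if v > 80 else D if v < 70 else G
            assert lab is expected


class TestRefinement:
    def test_single_run_identity(self):
        segs = refine_segments([D] * 40)
        assert segs == [Segment(0, 40, D)]

    def test_gap_flanked_by_disorder_becomes_disorder(self):
        segs = refine_segments([D] * 20 + [G] * 5 + [D] * 20)
        assert segs == [Segment(0, 45, D)]

    def test_gap_flanked_by_folded_becomes_folded(self):
        segs = refine_segments([F] * 20 + [G] * 5 + [F] * 20)
        assert segs == [Segment(0, 45, F)]

    def test_short_disordered_run_absorbed_into_folded(self):
        # 5 disordered residues (< min_run) demote to gap; a terminal gap not
        # adjacent to a disordered run relabels as folded
        segs = refine_segments([D] * 5 + [F] * 50)
        assert segs == [Segment(0, 55, F)]

    def test_mixed_flank_gap_becomes_folded(self):
        segs = refine_segments([D] * 20 + [G] * 5 + [F] * 20)
        assert segs == [Segment(0, 20, D), Segment(20, 45, F)]

    def test_terminal_gap_adjacent_to_disorder_becomes_disorder(self):
        segs = refine_segments([G] * 5 + [D] * 30)
        assert segs == [Segment(0, 35, D)]

    def test_no_gap_survives_and_tiles(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            labels = [rng.choice([F, D, G]) for _ in range(rng.integers(1, 120))]
            segs = refine_segments(labels)
            assert all(s.label is not G for s in segs)
            assert segs[0].start == 0 and segs[-1].end == len(labels)
            for a, b in zip(segs, segs[1:]):
                assert a.end == b.start and a.label != b.label

    def test_idempotent_fixed_point(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            labels = [rng.choice([F, D, G]) for _ in range(rng.integers(10, 150))]
            once = refine_segments(labels)
            twice = refine_segments(segments_to_labels(once))
            assert once == twice


class TestExtraction:
    def _trace(self, seq, plddt=None):
        return PlddtTrace("p1", seq, plddt if plddt is not None else [50.0] * len(seq))

    def test_long_protein_dropped(self):
        seq = "A" * 600
        segs = [Segment(0, 100, F), Segment(100, 150, D), Segment(150, 600, F)]
        assert extract_idr_records(self._trace(seq), segs) == []

    def test_entirely_disordered_protein_dropped(self):
        seq = "A" * 100
        assert extract_idr_records(self._trace(seq), [Segment(0, 100, D)]) == []

    def test_coordinates_one_based_inclusive(self):
        seq = "F" * 100 + "D" * 40 + "L" * 60
        segs = [Segment(0, 100, F), Segment(100, 140, D), Segment(140, 200, F)]
        (rec,) = extract_idr_records(self._trace(seq), segs)
        assert (rec.idr_start, rec.idr_end) == (101, 140)
        assert len(rec.n_context) == 100 and len(rec.c_context) == 60
        assert rec.full_sequence == seq

    def test_short_idr_dropped(self):
        seq = "A" * 80
        segs = [Segment(0, 30, F), Segment(30, 50, D), Segment(50, 80, F)]
        assert extract_idr_records(self._trace(seq), segs) == []

    def test_noncanonical_protein_skipped(self):
        seq = "A" * 50 + "X" + "A" * 49
        segs = [Segment(0, 40, D), Segment(40, 100, F)]
        assert extract_idr_records(self._trace(seq), segs) == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PlddtTrace("p", "AAAA", [50.0] * 3)


class TestEndToEnd:
    def test_noiseless_recovery_within_half_window(self):
        params = SegmentationParams()
        half = (params.window - 1) // 2
        hit = 0
        total = 0
        for seed in range(40):
            layout = SegmentLayout(
                segments=[("FOLDED", 90), ("DISORDERED", 60), ("FOLDED", 90)],
                folded_sd=0.0,
                disordered_sd=0.0,
                ramp=0,
                seed=seed,
            )
            trace, truth = synth_protein_with_plddt(layout)
            recs = curate_protein(trace, params)
            true_idr = [s for s in truth if s.label is Label.DISORDERED][0]
            total += 1
            for rec in recs:
                start0, end0 = rec.idr_start - 1, rec.idr_end
                if abs(start0 - true_idr.start) <= half and abs(end0 - true_idr.end) <= half:
                    hit += 1
        assert hit == total

    def test_noisy_recovery(self):
        # low-noise traces: boundaries within the smoothing half-window
        params = SegmentationParams()
        half = (params.window - 1) // 2
        ok = 0
        n = 200
        for seed in range(n):
            layout = SegmentLayout(
                segments=[("FOLDED", 80), ("DISORDERED", 70), ("FOLDED", 80)],
                folded_sd=2.0,
                disordered_sd=2.0,
                ramp=0,
                seed=1000 + seed,
            )
            trace, truth = synth_protein_with_plddt(layout)
            recs = curate_protein(trace, params)
            true_idr = [s for s in truth if s.label is Label.DISORDERED][0]
            if len(recs) == 1:
                rec = recs[0]
                if (
                    abs((rec.idr_start - 1) - true_idr.start) <= half
                    and abs(rec.idr_end - true_idr.end) <= half
                ):
                    ok += 1
        assert ok == n

    def test_concatenation_invariant(self):
        for seed in range(20):
            layout = SegmentLayout(
                segments=[("DISORDERED", 50), ("FOLDED", 100), ("DISORDERED", 40)],
                seed=seed,
            )
            trace, _ = synth_protein_with_plddt(layout)
            for rec in curate_protein(trace):
                assert rec.full_sequence == trace.sequence
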