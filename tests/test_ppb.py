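"""Moving-average, binarization, run-length cleaning and segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reptrack.cnn import ProbabilityStream
from reptrack.ppb import (
    PPBConfig, binarize, eliminate_peaks, extract_scenario, fill_gaps,
    moving_average, postprocess, streams_to_segments,
)
from reptrack.signals import ActivityLabel, Segment

BREAK, DIP, PULLUP, SQUAT = ActivityLabel


from oracles import epg_oracle


binary_strings = st.lists(st.integers(0, 1), min_size=1, max_size=120)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(moving_average(np.full(30, 2.5), 7), 2.5)

    def test_w1_is_identity(self, rng):
        y = rng.normal(size=40)
        np.testing.assert_allclose(moving_average(y, 1), y)

    def test_forward_window_with_truncated_tail(self):
        np.testing.assert_allclose(moving_average([0, 0, 2, 2], 2),
                                   [0, 1, 2, 2])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(1, 60), st.integers(1, 15), st.integers(0, 10 ** 6))
    def test_equals_direct_evaluation(self, n, w, seed):
        y = np.random.default_rng(seed).normal(size=n)
        got = moving_average(y, w)
        expect = [y[i:i + w].mean() for i in range(n)]
        np.testing.assert_allclose(got, expect, atol=1e-12)
        assert y.min() - 1e-12 <= got.min() and got.max() <= y.max() + 1e-12


class TestBinarize:
    @pytest.mark.parametrize("p,thr,expected", [
        ([1.0, 1.0], 0.5, [1, 1]),
        ([0.2, 0.5, 0.8], 0.5, [0, 1, 1]),   # >= convention at the threshold
        ([0.0, 0.3], 0.0, [1, 1]),
    ])
    def test_threshold_convention(self, p, thr, expected):
        np.testing.assert_array_equal(binarize(np.array(p), thr), expected)


class TestRunLengthCleaning:
    @pytest.mark.parametrize("b,delta,expected", [
        (np.ones(200, dtype=int), 90, np.ones(200, dtype=int)),
        ([0, 0, 1, 1, 0], 3, [0, 0, 0, 0, 0]),
        ([0, 1] * 10, 1, [0] * 20),  # strict: runs of exactly delta removed
    ])
    def test_eliminate_peaks_examples(self, b, delta, expected):
        np.testing.assert_array_equal(eliminate_peaks(np.array(b), delta),
                                      expected)

    @pytest.mark.parametrize("b,delta,expected", [
        (np.zeros(200, dtype=int), 60, np.zeros(200, dtype=int)),
        ([1, 1, 0, 0, 1, 1], 3, [1, 1, 1, 1, 1, 1]),
    ])
    def test_fill_gaps_examples(self, b, delta, expected):
        np.testing.assert_array_equal(fill_gaps(np.array(b), delta),
                                      expected)

    def test_gap_of_exactly_delta_plus_one_preserved(self):
        b = np.array([1] * 5 + [0] * 4 + [1] * 5)
        np.testing.assert_array_equal(fill_gaps(b, 3), b)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(binary_strings, st.integers(1, 20))
    def test_equals_brute_force_oracle(self, b, delta):
        b = np.array(b, dtype=np.int8)
        np.testing.assert_array_equal(eliminate_peaks(b, delta),
                                      epg_oracle(b, 1, delta))
        np.testing.assert_array_equal(fill_gaps(b, delta),
                                      epg_oracle(b, 0, delta))

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(binary_strings, st.integers(1, 20), st.integers(1, 20))
    def test_idempotence(self, b, d1, d0):
        b = np.array(b, dtype=np.int8)
        p = eliminate_peaks(b, d1)
        np.testing.assert_array_equal(eliminate_peaks(p, d1), p)
        g = fill_gaps(b, d0)
        np.testing.assert_array_equal(fill_gaps(g, d0), g)


def _stream_from_mask(mask_by_class, n):
    """Build a ProbabilityStream whose per-sample view equals the given
    per-class probability matrix (rows n-49, alignment-compensated)."""
    probs = np.stack(mask_by_class, axis=1).astype(float)
    return probs  # postprocess also accepts the raw (n, 4) matrix


class TestPostprocess:
    def test_short_false_positive_burst_removed(self):
        n = 800
        dip = np.zeros(n)
        dip[100:500] = 1.0          # one real dip activation
        brk = 1.0 - dip
        pullup = np.zeros(n)
        pullup[300:330] = 1.0       # 30-sample false positive inside the dip
        squat = np.zeros(n)
        binary = postprocess(np.stack([brk, dip, pullup, squat], axis=1),
                             PPBConfig())
        assert binary[:, 2].sum() == 0          # burst eliminated (30 < 90)
        assert binary[300:400, 1].all()         # dip stream intact

    def test_short_dropout_filled(self):
        n = 800
        squat = np.zeros(n)
        squat[100:600] = 1.0
        squat[340:380] = 0.0        # 40-sample dropout
        binary = postprocess(
            np.stack([1 - squat, np.zeros(n), np.zeros(n), squat], axis=1),
            PPBConfig())
        assert binary[340:380, 3].all()         # gap filled (40 < 60)

    def test_no_exercise_segment_shorter_than_delta1(self, rng):
        probs = rng.dirichlet(np.ones(4) * 0.3, size=1500)
        binary = postprocess(probs, PPBConfig())
        segs = streams_to_segments(binary)
        for s in segs:
            if s.label != BREAK:
                assert s.length > 90

    def test_clean_protocol_recovered(self, clean_config, tiny_corpus):
        """Idealized probabilities (one-hot ground truth) pass through the
        block unchanged up to the documented boundary behaviour."""
        from reptrack.simulate import generate_dataset
        sig, truth = generate_dataset(clean_config, 1, seed=5)[0]
        onehot = np.eye(4)[truth.sample_labels()]
        binary = postprocess(onehot, PPBConfig())
        segs = streams_to_segments(binary)
        assert extract_scenario(segs) == truth.scenario


class TestSegments:
    def test_disjoint_activations(self):
        n = 600
        dip = np.zeros(n, dtype=int)
        dip[50:250] = 1
        squat = np.zeros(n, dtype=int)
        squat[350:550] = 1
        binary = np.stack([np.zeros(n, int), dip, np.zeros(n, int), squat],
                          axis=1)
        segs = streams_to_segments(binary)
        labels = [(s.label, s.start, s.end) for s in segs]
        assert labels == [
            (BREAK, 0, 50), (DIP, 50, 250), (BREAK, 250, 350),
            (SQUAT, 350, 550), (BREAK, 550, 600)]

    def test_no_activation_is_single_break(self):
        binary = np.zeros((300, 4), dtype=int)
        segs = streams_to_segments(binary)
        assert len(segs) == 1 and segs[0].label == BREAK

    def test_overlap_resolved_by_longest_current_run(self):
        n = 300
        dip = np.zeros(n, dtype=int)
        dip[0:110] = 1              # active since sample 0
        squat = np.zeros(n, dtype=int)
        squat[100:200] = 1          # joins at 100, overlap 100..110
        binary = np.stack([np.zeros(n, int), dip, np.zeros(n, int), squat],
                          axis=1)
        segs = streams_to_segments(binary)
        # during the overlap the dip run is longer, so dip holds until 110
        assert segs[0] == Segment(DIP, 0, 110)
        assert segs[1] == Segment(SQUAT, 110, 200)

    def test_overlap_rule_matches_hand_simulation(self, rng):
        n = 400
        binary = np.zeros((n, 4), dtype=np.int8)
        for k in range(1, 4):
            on = rng.random(8) < 0.5
            bounds = np.sort(rng.integers(0, n, 16))
            for i in range(8):
                if on[i]:
                    binary[bounds[2 * i]:bounds[2 * i + 1], k] = 1
        segs = streams_to_segments(binary)
        # hand simulation of the stated per-sample rule
        expect = []
        run = {1: 0, 2: 0, 3: 0}
        for i in range(n):
            active = [k for k in (1, 2, 3) if binary[i, k]]
            for k in (1, 2, 3):
                run[k] = run[k] + 1 if binary[i, k] else 0
            if not active:
                expect.append(0)
            else:
                best = max(active, key=lambda k: (run[k], -k))
                expect.append(best)
        got = np.concatenate([[int(s.label)] * s.length for s in segs])
        np.testing.assert_array_equal(got, expect)

    def test_segments_tile_range(self, rng):
        binary = (rng.random((500, 4)) < 0.3).astype(np.int8)
        segs = streams_to_segments(binary)
        assert segs[0].start == 0 and segs[-1].end == 500
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start and a.label != b.label


class TestScenario:
    def test_example_sequence(self):
        segs = (Segment(BREAK, 0, 100), Segment(PULLUP, 100, 300),
                Segment(BREAK, 300, 400), Segment(DIP, 400, 600),
                Segment(BREAK, 600, 700), Segment(SQUAT, 700, 900),
                Segment(BREAK, 900, 1000))
        assert extract_scenario(segs) == (PULLUP, DIP, SQUAT)

    def test_all_break_is_empty(self):
        assert extract_scenario((Segment(BREAK, 0, 500),)) == ()

    def test_repeated_activity_kept(self):
        segs = (Segment(BREAK, 0, 100), Segment(SQUAT, 100, 300),
                Segment(BREAK, 300, 400), Segment(SQUAT, 400, 600),
                Segment(BREAK, 600, 700))
        assert extract_scenario(segs) == (SQUAT, SQUAT)
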