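import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methcal.calcium import (
    ActivitySummary,
    DetectionParams,
    EventSet,
    activity_rate,
    compute_threshold,
    deduplicate_events,
    detect_candidates,
    detect_events,
    evaluate_detection,
    filter_by_threshold,
    normalize_dff,
)
from conftest import make_norm, make_raw
from oracles import brute_force_detect, percentile_linear


class TestNormalizeDff:
    def test_constant_trace(self):
        norm = normalize_dff(make_raw([5, 5, 5, 5]))
        assert norm.f0 == 5.0
        np.testing.assert_array_equal(norm.dff, np.zeros(4))

    def test_scale_invariance(self):
        x = np.array([3.0, 7.0, 4.0, 9.0, 2.0, 5.0])
        a = normalize_dff(make_raw(x))
        b = normalize_dff(make_raw(3.0 * x))
        np.testing.assert_allclose(a.dff, b.dff, atol=1e-12)

    def test_percentile_convention(self):
        trace = make_raw(np.arange(1.0, 101.0))
        norm = normalize_dff(trace)
        assert norm.f0 == pytest.approx(5.95)
        assert norm.dff[0] == pytest.approx((1 - 5.95) / 5.95)

    def test_matches_independent_percentile_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 10, 57)
        norm = normalize_dff(make_raw(x))
        assert norm.f0 == pytest.approx(percentile_linear(list(x), 5.0))

    def test_rejects_short_trace(self):
        with pytest.raises(ValueError, match="4 samples"):
            make_raw([1, 2, 3])

    def test_rejects_nonpositive_intensity(self):
        with pytest.raises(ValueError, match="positive"):
            make_raw([1, -2, 3, 4])

    def test_zero_percentile_uses_minimum(self):
        trace = make_raw([2.0, 5.0, 5.0, 5.0])
        norm = normalize_dff(trace, DetectionParams(f0_percentile=0.0))
        assert norm.f0 == 2.0
        assert norm.dff.min() == 0.0


class TestComputeThreshold:
    def test_floor_when_mad_zero(self):
        assert compute_threshold(make_norm(np.zeros(10))) == pytest.approx(0.1)

    def test_hand_arithmetic(self):
        assert compute_threshold(make_norm([-1.0, 0.0, 1.0])) == pytest.approx(2.0)

    def test_floor_wins_on_worked_trace(self, worked_dff):
        # sorted |dff - median|: MAD = 0.025 -> 2*MAD = 0.05 < 0.1
        assert compute_threshold(make_norm(worked_dff)) == pytest.approx(0.1)

    def test_mad_unscaled(self):
        rng = np.random.default_rng(1)
        dff = rng.normal(0, 1, 1001)
        med = np.median(dff)
        mad = np.median(np.abs(dff - med))
        assert compute_threshold(make_norm(dff)) == pytest.approx(2.0 * mad)


class TestDetectCandidates:
    def test_monotone_trace_has_none(self):
        assert detect_candidates(make_norm(np.arange(10.0))).size == 0

    def test_worked_trace_single_candidate(self, worked_dff):
        np.testing.assert_array_equal(detect_candidates(make_norm(worked_dff)), [3])

    def test_twin_peaks(self, twin_peak_dff):
        np.testing.assert_array_equal(detect_candidates(make_norm(twin_peak_dff)), [1, 4])

    def test_edges_excluded(self):
        # peak shapes at the very edges must not produce candidates
        dff = np.array([1.0, 0.5, 0.2, 0.4, 1.0, 0.9])
        cands = detect_candidates(make_norm(dff))
        assert 0 not in cands and len(dff) - 1 not in cands and len(dff) - 2 not in cands

    def test_onset_anchor_shifts_left(self, worked_dff):
        np.testing.assert_array_equal(
            detect_candidates(make_norm(worked_dff), anchor="onset"), [2]
        )

    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=4, max_size=40))
    def test_matches_brute_force_triple_scan(self, dff):
        from oracles import brute_force_candidates

        got = detect_candidates(make_norm(dff)).tolist()
        assert got == brute_force_candidates(dff)


class TestFilterByThreshold:
    def test_retains_above(self, worked_dff):
        norm = make_norm(worked_dff)
        np.testing.assert_array_equal(filter_by_threshold([3], norm, 0.1), [3])

    def test_exact_threshold_rejected(self):
        norm = make_norm([0.0, 0.1, 0.5, 0.5, 0.2, 0.0])
        assert filter_by_threshold([2], norm, 0.5).size == 0

    def test_empty_input(self, worked_dff):
        assert filter_by_threshold([], make_norm(worked_dff), 0.1).size == 0


class TestDeduplicateEvents:
    def test_merge_when_no_subthreshold_dip(self, twin_peak_dff):
        events = deduplicate_events([1, 4], make_norm(twin_peak_dff), threshold=0.4)
        # inter-event min 0.42 >= 0.4 -> merged; tie 0.5 vs 0.5 -> earliest
        assert events.event_indices == (1,)
        assert events.amplitudes == (0.5,)

    def test_kept_when_dip_below_threshold(self, twin_peak_dff):
        events = deduplicate_events([1, 4], make_norm(twin_peak_dff), threshold=0.43)
        assert events.event_indices == (1, 4)

    def test_single_event_unchanged(self, worked_dff):
        events = deduplicate_events([3], make_norm(worked_dff), threshold=0.1)
        assert events.event_indices == (3,)

    def test_higher_amplitude_wins_merge(self):
        dff = np.array([0.0, 0.5, 0.45, 0.7, 0.2, 0.0, 0.0, 0.0])
        events = deduplicate_events([1, 3], make_norm(dff), threshold=0.4)
        assert events.event_indices == (3,)

    def test_empty(self, worked_dff):
        events = deduplicate_events([], make_norm(worked_dff), threshold=0.1)
        assert events.n_events == 0


class TestEventSetInvariants:
    def test_amplitude_must_exceed_threshold(self):
        with pytest.raises(ValueError, match="exceed"):
            EventSet(roi_id="r", event_indices=(1,), amplitudes=(0.1,), threshold=0.1)

    def test_indices_strictly_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            EventSet(roi_id="r", event_indices=(3, 3), amplitudes=(0.5, 0.5), threshold=0.1)


class TestActivityRate:
    def test_six_events_two_minutes(self):
        es = EventSet("r", tuple(range(1, 7)), (0.5,) * 6, 0.1)
        summary = activity_rate(es, 120.0)
        assert summary.rate == pytest.approx(3.0)
        assert summary.included

    def test_twelve_events_four_minutes(self):
        es = EventSet("r", tuple(range(1, 13)), (0.5,) * 12, 0.1)
        assert activity_rate(es, 240.0).rate == pytest.approx(3.0)

    def test_zero_events_excluded(self):
        es = EventSet("r", (), (), 0.1)
        summary = activity_rate(es, 120.0)
        assert summary.n_events == 0
        assert not summary.included

    def test_nonpositive_duration_rejected(self):
        es = EventSet("r", (), (), 0.1)
        with pytest.raises(ValueError):
            activity_rate(es, 0.0)


class TestDetectEvents:
    def test_flat_trace_excluded(self):
        events, summary = detect_events(make_raw([7.0] * 20))
        assert events.n_events == 0
        assert not summary.included

    def test_worked_trace_end_to_end(self, worked_dff):
        raw = make_raw(100.0 * (1.0 + worked_dff))
        events, summary = detect_events(raw)
        assert events.event_indices == (3,)
        assert summary.n_events == 1
        assert summary.rate == pytest.approx(1 / (10 / 60))
        assert summary.included

    def test_stagewise_composition(self, twin_peak_dff):
        raw = make_raw(50.0 * (1.0 + twin_peak_dff))
        norm = normalize_dff(raw)
        thr = compute_threshold(norm)
        staged = deduplicate_events(
            filter_by_threshold(detect_candidates(norm), norm, thr), norm, thr
        )
        events, _ = detect_events(raw)
        assert events == staged


class TestEvaluateDetection:
    def test_perfect(self):
        score = evaluate_detection([3, 10, 20], [3, 10, 20], 3)
        assert (score.precision, score.recall) == (1.0, 1.0)

    def test_empty_detected(self):
        score = evaluate_detection([], [5, 10], 3)
        assert score.precision == 0.0
        assert not score.precision_defined
        assert score.recall == 0.0

    def test_within_tolerance(self):
        score = evaluate_detection([10], [12], 3)
        assert (score.precision, score.recall) == (1.0, 1.0)

    def test_outside_tolerance(self):
        score = evaluate_detection([10], [14], 3)
        assert (score.precision, score.recall) == (0.0, 0.0)

    def test_one_to_one_matching(self):
        # two detections near one truth: only one may match
        score = evaluate_detection([10, 11], [10], 3)
        assert score.n_matched == 1
        assert score.precision == pytest.approx(0.5)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            evaluate_detection([1], [1], -1)


def random_bumpy_trace(rng, n):
    """Uniform noise plus occasional injected bumps, positive everywhere."""
    base = rng.uniform(0.9, 1.1, n)
    for _ in range(rng.integers(0, 4)):
        t0 = rng.integers(1, max(2, n - 2))
        amp = rng.uniform(0.1, 1.0)
        width = int(rng.integers(1, 5))
        for j in range(width):
            if t0 + j < n:
                base[t0 + j] += amp * np.exp(-j / 2.0)
    return base


class TestOracleEquivalence:
    def test_staged_equals_brute_force_on_random_traces(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n = int(rng.integers(4, 51))
            raw = make_raw(random_bumpy_trace(rng, n))
            events, _ = detect_events(raw)
            expected, expected_thr = brute_force_detect(list(raw.intensities))
            assert list(events.event_indices) == expected
            assert events.threshold == pytest.approx(expected_thr)


class TestMonotonicityInFloor:
    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_raising_floor_never_adds_retained_candidates(self, seed):
        """Before de-duplication the count of supra-threshold candidates is
        non-increasing in the floor. (After de-duplication this is provably
        false: a higher threshold can split a merged group when the valley
        between two peaks dips below the new threshold but not the old one —
        see the regression test below.)"""
        rng = np.random.default_rng(seed)
        raw = make_raw(random_bumpy_trace(rng, int(rng.integers(8, 60))))
        norm = normalize_dff(raw)
        candidates = detect_candidates(norm)
        counts = []
        for floor in (0.05, 0.1, 0.2, 0.4):
            thr = max(compute_threshold(norm), floor)
            counts.append(filter_by_threshold(candidates, norm, thr).size)
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_group_splitting_counterexample(self):
        """Pinned counterexample: raising the floor from 0.2 to 0.4 splits a
        two-peak group whose valley lies between the two thresholds."""
        rng = np.random.default_rng(299)
        raw = make_raw(random_bumpy_trace(rng, int(rng.integers(8, 60))))
        low, _ = detect_events(raw, DetectionParams(threshold_floor=0.2))
        high, _ = detect_events(raw, DetectionParams(threshold_floor=0.4))
        assert low.event_indices == (25,)
        assert high.event_indices == (22, 25)


class TestRetainedEventInvariants:
    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_strict_exceedance_and_interevent_dip(self, seed):
        rng = np.random.default_rng(seed)
        raw = make_raw(random_bumpy_trace(rng, int(rng.integers(8, 80))))
        events, _ = detect_events(raw)
        norm = normalize_dff(raw)
        for idx, amp in zip(events.event_indices, events.amplitudes):
            assert amp > events.threshold
            assert norm.dff[idx] == pytest.approx(amp)
        for a, b in zip(events.event_indices, events.event_indices[1:]):
            assert norm.dff[a + 1 : b].min() < events.threshold
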