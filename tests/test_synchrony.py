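"""Bout detection, window placement, Pearson classification, frequency recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wingsync import (
    AnalysisParams,
    Recording,
    SimConfig,
    SyncEvent,
    analyze_recording,
    classify_event,
    detect_flight_bouts,
    estimate_wingbeat_frequency,
    sample_windows,
    simulate_recording,
    summarize_events,
    window_correlation,
)


def two_pass_pearson(x, y):
    """Independent product-moment oracle: plain two-pass textbook formula."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


class TestBoutDetection:
    def test_constant_plus_noise_has_no_bouts(self):
        rng = np.random.default_rng(0)
        level = 500 + rng.normal(0, 2, 50_000)
        rec = Recording(fs_hz=10_000.0,
                        left=np.round(level).astype(int),
                        right=np.round(level + rng.normal(0, 2, 50_000)).astype(int))
        assert detect_flight_bouts(rec) == []

    def test_continuous_flight_is_one_full_bout(self, noiseless_recording):
        bouts = detect_flight_bouts(noiseless_recording)
        assert len(bouts) == 1
        assert bouts[0].n_samples >= 0.99 * len(noiseless_recording)

    def test_intermittent_bout_count_matches_ground_truth(self):
        cfg = SimConfig(coupling_mode="intermittent", duration_s=10.0,
                        noise_sd=2.0, bout_on_s=0.2, bout_off_s=0.2, seed=5)
        rec = simulate_recording(cfg)
        detected = detect_flight_bouts(rec)
        assert abs(len(detected) - len(rec.meta["true_bouts"])) <= 1

    def test_no_flight_recording_has_no_bouts(self, no_flight_recording):
        assert detect_flight_bouts(no_flight_recording) == []

    def test_recording_shorter_than_rolling_window_rejected(self):
        rec = Recording(fs_hz=10_000.0, left=np.arange(100), right=np.arange(100))
        with pytest.raises(ValueError, match="rolling window"):
            detect_flight_bouts(rec)

    def test_bouts_sorted_and_disjoint(self):
        cfg = SimConfig(coupling_mode="intermittent", duration_s=8.0,
                        noise_sd=2.0, bout_on_s=0.3, bout_off_s=0.3, seed=9)
        bouts = detect_flight_bouts(simulate_recording(cfg))
        for prev, nxt in zip(bouts, bouts[1:]):
            assert prev.end_sample <= nxt.start_sample


class TestWindowSampling:
    def test_requested_window_count_on_long_recording(self, locked_recording):
        bouts = detect_flight_bouts(locked_recording)
        draw = sample_windows(locked_recording, bouts, AnalysisParams(seed=1))
        assert len(draw.starts) == 50 and not draw.shortfall

    def test_no_flight_yields_empty_draw_with_flag(self, no_flight_recording):
        draw = sample_windows(no_flight_recording, [], AnalysisParams(seed=1))
        assert draw.starts == () and draw.shortfall

    def test_same_seed_reproduces_starts(self, locked_recording):
        bouts = detect_flight_bouts(locked_recording)
        a = sample_windows(locked_recording, bouts, AnalysisParams(seed=8))
        b = sample_windows(locked_recording, bouts, AnalysisParams(seed=8))
        assert a.starts == b.starts

    def test_windows_lie_fully_inside_bouts(self):
        cfg = SimConfig(coupling_mode="intermittent", duration_s=8.0,
                        noise_sd=2.0, bout_on_s=0.3, bout_off_s=0.3, seed=21)
        rec = simulate_recording(cfg)
        bouts = detect_flight_bouts(rec)
        params = AnalysisParams(seed=2)
        w = params.window_samples(rec.fs_hz)
        draw = sample_windows(rec, bouts, params)
        assert draw.starts
        for s in draw.starts:
            assert any(b.start_sample <= s and s + w <= b.end_sample for b in bouts)

    def test_window_too_short_for_three_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            AnalysisParams(window_ms=5.0).window_samples(fs_hz=400.0)


class TestWindowCorrelation:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),       # identity
        ([1, 2, 3, 4], [2, 4, 6, 8], 1.0),       # positive affine
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),       # direct product-moment value
        ([1, 2, 3, 4], [-2, -4, -6, -8], -1.0),  # negative affine
    ])
    def test_known_values(self, x, y, expected):
        assert window_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        assert math.isnan(window_correlation([1, 2, 3, 4], [5, 5, 5, 5]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            window_correlation([1, 2, 3], [1, 2, 3, 4])

    def test_matches_two_pass_oracle_on_random_segments(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(3, 80))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            assert window_correlation(x, y) == pytest.approx(
                two_pass_pearson(x, y), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 1023), min_size=5, max_size=50),
           st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    def test_invariant_under_positive_affine_transform(self, values, scale, shift):
        rng = np.random.default_rng(sum(values))
        x = np.array(values, dtype=float)
        y = x + rng.normal(0, 1, x.size)
        r = window_correlation(x, y)
        if math.isnan(r):
            return
        assert window_correlation(scale * x + shift, y) == pytest.approx(r, abs=1e-9)
        assert window_correlation(-x, y) == pytest.approx(-r, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize("r, expected", [
        (0.51, "synchronized"),
        (0.5, "unsynchronized"),   # threshold is strict
        (-0.6, "unsynchronized"),
        (float("nan"), "degenerate"),
    ])
    def test_labels(self, r, expected):
        assert classify_event(r, 0.5) == expected

    def test_synchronized_count_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        rs = rng.uniform(-1, 1, 200)
        counts = [sum(classify_event(r, t) == "synchronized" for r in rs)
                  for t in np.linspace(-1, 1, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSummary:
    @staticmethod
    def _events(n_sync, n_unsync, n_deg=0):
        ev = [SyncEvent(0, 50, 0.9, "synchronized")] * n_sync
        ev += [SyncEvent(0, 50, 0.1, "unsynchronized")] * n_unsync
        ev += [SyncEvent(0, 50, float("nan"), "degenerate")] * n_deg
        return ev

    def test_all_synchronized_gives_one(self):
        s = summarize_events(self._events(500, 0))
        assert s.proportion_synchronized == 1.0 and s.n_events == 500

    def test_simple_proportion(self):
        assert summarize_events(self._events(40, 10)).proportion_synchronized == 0.8

    def test_ci_matches_exact_binomial(self):
        s = summarize_events(self._events(38, 62))
        assert s.proportion_synchronized == pytest.approx(0.38)
        # bisection oracle on the binomial tails
        from scipy.stats import binom
        def lower(k, n, a=0.025):
            lo, hi = 0.0, 1.0
            for _ in range(60):
                mid = (lo + hi) / 2
                if binom.sf(k - 1, n, mid) < a:
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2
        def upper(k, n, a=0.025):
            lo, hi = 0.0, 1.0
            for _ in range(60):
                mid = (lo + hi) / 2
                if binom.cdf(k, n, mid) < a:
                    hi = mid
                else:
                    lo = mid
            return (lo + hi) / 2
        assert s.ci_low == pytest.approx(lower(38, 100), abs=1e-9)
        assert s.ci_high == pytest.approx(upper(38, 100), abs=1e-9)

    def test_degenerate_events_excluded_from_denominator(self):
        s = summarize_events(self._events(30, 10, n_deg=10))
        assert s.n_degenerate == 10
        assert s.proportion_synchronized == pytest.approx(0.75)

    def test_all_degenerate_rejected(self):
        with pytest.raises(ValueError, match="non-degenerate"):
            summarize_events(self._events(0, 0, n_deg=5))


class TestEndToEnd:
    def test_locked_noiseless_fully_synchronized(self, noiseless_recording):
        events = analyze_recording(noiseless_recording, AnalysisParams(seed=3))
        assert all(e.r == pytest.approx(1.0, abs=1e-12) for e in events)
        assert summarize_events(events).proportion_synchronized == 1.0

    def test_drifting_wings_mostly_unsynchronized(self, drift_recording):
        events = analyze_recording(drift_recording, AnalysisParams(seed=7))
        assert summarize_events(events).proportion_synchronized < 0.5


class TestFrequencyEstimation:
    def test_symmetric_stroke_reports_beat_not_double(self):
        cfg = SimConfig(beat_frequency_hz=200.0, rest_distance_mm=0.635,
                        duration_s=4.0, noise_sd=2.0, seed=1)
        rec = simulate_recording(cfg)
        f = estimate_wingbeat_frequency(rec, detect_flight_bouts(rec))
        assert f == pytest.approx(200.0, rel=0.05)

    def test_asymmetric_stroke_recovers_beat(self):
        cfg = SimConfig(beat_frequency_hz=150.0, rest_distance_mm=0.9,
                        duration_s=4.0, noise_sd=2.0, seed=3)
        rec = simulate_recording(cfg)
        f = estimate_wingbeat_frequency(rec, detect_flight_bouts(rec))
        assert f == pytest.approx(150.0, rel=0.05)

    def test_flat_signal_rejected(self):
        rec = Recording(fs_hz=10_000.0, left=np.full(20_000, 512),
                        right=np.full(20_000, 512))
        with pytest.raises(ValueError):
            estimate_wingbeat_frequency(rec, [])

    def test_no_bouts_rejected(self, no_flight_recording):
        with pytest.raises(ValueError, match="bout"):
            estimate_wingbeat_frequency(no_flight_recording, [])
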