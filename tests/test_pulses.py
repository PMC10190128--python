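"""Pulse processing: filtering, background, detection, ladder fits,
coincidence matching."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ladderflow import (ChannelConfig, DetectionSettings, RawTrace,
                        detect_events, estimate_background, fit_ladder,
                        match_channels, median_filter, render_trace)
from ladderflow.pulses import LadderFit, PulseEvent

from conftest import make_cell

SR = 500_000.0


def trace_of(values, sr=SR) -> RawTrace:
    return RawTrace(values=np.atleast_2d(np.asarray(values, dtype=float)),
                    sample_rate_hz=sr)


def median_oracle(x: np.ndarray, w: int) -> np.ndarray:
    """Plain sliding-window median with replicate padding."""
    pad = w // 2
    xp = np.concatenate([[x[0]] * pad, x, [x[-1]] * pad])
    return np.array([np.median(xp[i:i + w]) for i in range(len(x))])


def detect_oracle(vals: np.ndarray, mean: float, threshold: float,
                  min_len: int) -> list[tuple[int, int]]:
    """Plain scan: suprathreshold runs of min_len, extended to the mean
    crossing, overlaps merged."""
    spans = []
    i, n = 0, len(vals)
    while i < n:
        if vals[i] > threshold:
            j = i
            while j < n and vals[j] > threshold:
                j += 1
            if j - i >= min_len:
                s, e = i, j
                while s > 0 and vals[s - 1] > mean:
                    s -= 1
                while e < n and vals[e] > mean:
                    e += 1
                if spans and s <= spans[-1][1]:
                    spans[-1] = (spans[-1][0], max(spans[-1][1], e))
                else:
                    spans.append((s, e))
            i = j
        else:
            i += 1
    return spans


class TestMedianFilter:
    def test_constant_trace_invariant(self):
        trace = trace_of([5.0] * 200)
        out = median_filter(trace, 50)
        assert np.array_equal(out.values, trace.values)

    def test_single_spike_removed(self):
        out = median_filter(trace_of([0, 0, 10, 0, 0]), 3)
        assert np.array_equal(out.values[0], np.zeros(5))

    def test_monotone_ramp_preserved_away_from_edges(self):
        ramp = np.arange(100.0)
        out = median_filter(trace_of(ramp), 3)
        assert np.array_equal(out.values[0][1:-1], ramp[1:-1])

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(2.0, 1.5, 3000)
        x[500:600] += 30
        out = median_filter(trace_of(x), 51)
        assert np.allclose(out.values[0], median_oracle(x, 51))

    def test_even_window_widened_to_odd(self, rng):
        x = rng.normal(0, 1, 500)
        assert np.array_equal(median_filter(trace_of(x), 50).values,
                              median_filter(trace_of(x), 51).values)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            median_filter(trace_of([1.0, 2.0]), 5)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 4))
    def test_output_range_within_input_range(self, seed, half_w):
        x = np.random.default_rng(seed).normal(0, 1, 64)
        out = median_filter(trace_of(x), 2 * half_w + 1).values[0]
        assert out.min() >= x.min() - 1e-12
        assert out.max() <= x.max() + 1e-12


class TestEstimateBackground:
    def test_constant_trace_zero_variance_flagged(self):
        bg = estimate_background(trace_of([2.0] * 100))
        assert bg.mean[0] == 2.0
        assert bg.sd[0] == 0.0
        assert bg.threshold[0] == 2.0
        assert bg.zero_variance

    def test_threshold_formula_on_constructed_moments(self):
        # alternating 1, 3 -> mean 2, sd 1 -> threshold 5 with k = 3
        bg = estimate_background(trace_of([1.0, 3.0] * 500), threshold_k=3.0)
        assert bg.mean[0] == pytest.approx(2.0)
        assert bg.sd[0] == pytest.approx(1.0)
        assert bg.threshold[0] == pytest.approx(5.0)

    def test_gaussian_noise_monte_carlo(self):
        x = np.random.default_rng(77).normal(0.0, 1.0, 100_000)
        bg = estimate_background(trace_of(x))
        assert abs(bg.mean[0]) < 0.02
        assert abs(bg.sd[0] - 1.0) < 0.02
        assert abs(bg.threshold[0] - 3.0) < 0.08

    def test_pulses_do_not_inflate_threshold(self, default_cfg, small_params):
        """Threshold from a busy trace stays close to the pulse-free one."""
        from ladderflow import sample_population
        cells = sample_population(small_params, 50, seed=2)
        busy = render_trace(cells, default_cfg, seed=3)
        quiet = render_trace([], default_cfg, seed=3, duration_s=0.1)
        thr_busy = estimate_background(busy).threshold
        thr_quiet = estimate_background(quiet).threshold
        assert np.all(np.abs(thr_busy - thr_quiet) < 1.0)


class TestDetectEvents:
    def test_pure_baseline_no_events(self, default_cfg):
        trace = render_trace([], default_cfg, seed=1, duration_s=0.05)
        filtered = median_filter(trace, 51)
        events = detect_events(filtered, DetectionSettings())
        assert all(len(ch) == 0 for ch in events)

    def test_single_noiseless_trapezoid_spans_support(self):
        cfg = ChannelConfig(noise_sd_mV=0.0, baseline_mV=0.0,
                            gain=(1e-3,) * 3)
        cell = make_cell(copies=(30000, 30000, 30000))
        trace = render_trace([cell], cfg, seed=0)
        events = detect_events(trace, DetectionSettings())
        for ch in events:
            assert len(ch) == 1
            support = np.flatnonzero(trace.values[0] > 0)
            assert ch[0].start == support[0]
            assert ch[0].end == support[-1] + 1

    def test_rendered_pulse_count_recovered(self, small_params, default_cfg):
        from ladderflow import sample_population
        cells = sample_population(small_params, 20, seed=5)
        trace = render_trace(cells, default_cfg, seed=6)
        filtered = median_filter(trace, 51)
        events = detect_events(filtered, DetectionSettings())
        assert [len(ch) for ch in events] == [20, 20, 20]

    def test_equivalent_to_brute_force_scan(self, rng):
        """Detection on an arbitrary 1e5-sample noisy trace equals a plain
        suprathreshold scan with the same statistics."""
        x = rng.normal(2.0, 1.5, 100_000)
        for start in (5_000, 30_000, 31_500, 80_000):
            x[start:start + 900] += 40.0
        trace = trace_of(x)
        settings = DetectionSettings(min_event_samples=100)
        bg = estimate_background(trace, settings.threshold_k)
        events = detect_events(trace, settings, bg)[0]
        oracle = detect_oracle(x, bg.mean[0], bg.threshold[0], 100)
        assert [(e.start, e.end) for e in events] == oracle

    def test_event_count_never_exceeds_injected(self, small_params,
                                                default_cfg):
        from ladderflow import sample_population
        for seed in range(3):
            cells = sample_population(small_params, 15, seed=seed)
            trace = render_trace(cells, default_cfg, seed=seed + 100)
            filtered = median_filter(trace, 51)
            events = detect_events(filtered, DetectionSettings())
            assert all(len(ch) <= 15 for ch in events)

    def test_long_events_flagged_not_excluded_by_default(self):
        x = np.zeros(60_000)
        x[1000:1400] = 30.0   # typical events
        x[5000:5400] = 30.0
        x[10000:10400] = 30.0
        x[20000:40000] = 30.0  # one 50x longer run
        settings = DetectionSettings(min_event_samples=100)
        events = detect_events(trace_of(x + 1e-6), settings)[0]
        assert len(events) == 4
        assert [e.flagged_long for e in events] == [False] * 3 + [True]
        settings_excl = DetectionSettings(min_event_samples=100,
                                          exclude_long_events=True)
        assert len(detect_events(trace_of(x + 1e-6), settings_excl)[0]) == 3


class TestFitLadder:
    @staticmethod
    def render_single(t_a, t_s, t_d, amp, noise=0.0, seed=0, sr=SR):
        dt = 1e3 / sr
        total = t_a + t_s + t_d
        pad = max(int(0.2e-3 * sr), 50)
        n = int(total / dt) + 2 * pad
        t = np.arange(n) * dt
        t0 = pad * dt
        knots = [t0, t0 + max(t_a, 1e-9), t0 + max(t_a, 1e-9) + t_s,
                 t0 + max(t_a, 1e-9) + t_s + max(t_d, 1e-9)]
        y = amp * np.interp(t, knots, [0, 1, 1, 0], left=0, right=0)
        if noise:
            y = y + np.random.default_rng(seed).normal(0, noise, n)
        return PulseEvent(channel=0, start=0, end=n, peak_mV=float(y.max()),
                          segment=y)

    def test_noiseless_trapezoid_recovered_exactly(self):
        event = self.render_single(0.5, 2.0, 0.5, 30.0)
        fit = fit_ladder(event, SR)
        dt_ms = 1e3 / SR
        assert fit.t_a_ms == pytest.approx(0.5, abs=dt_ms)
        assert fit.t_s_ms == pytest.approx(2.0, abs=dt_ms)
        assert fit.t_d_ms == pytest.approx(0.5, abs=dt_ms)
        assert fit.i_f_mV == pytest.approx(30.0, abs=0.1)

    def test_rectangle_degenerate_trapezoid(self):
        event = self.render_single(0.0, 2.0, 0.0, 25.0)
        fit = fit_ladder(event, SR)
        dt_ms = 1e3 / SR
        assert fit.t_a_ms <= dt_ms
        assert fit.t_d_ms <= dt_ms
        assert fit.i_f_mV == pytest.approx(25.0, abs=0.1)

    def test_plateau_unbiased_under_noise(self):
        """Mean fitted plateau over noisy replicates is within 3 SEM of
        truth."""
        fits = [fit_ladder(self.render_single(0.5, 2.0, 0.5, 30.0,
                                              noise=2.0, seed=s), SR)
                for s in range(200)]
        plateaus = np.array([f.i_f_mV for f in fits])
        sem = plateaus.std(ddof=1) / np.sqrt(len(plateaus))
        assert abs(plateaus.mean() - 30.0) < 3 * sem

    def test_generator_round_trip_noiseless(self):
        """For rendered generator pulses the four features come back within
        one sample period / 0.1 mV."""
        cfg = ChannelConfig(noise_sd_mV=0.0, baseline_mV=0.0,
                            gain=(1e-3,) * 3)
        cell = make_cell(copies=(30000, 20000, 10000), diameter=15.0,
                         velocity=15.0)
        trace = render_trace([cell], cfg, seed=0)
        events = detect_events(trace, DetectionSettings())
        dt_ms = 1e3 / SR
        for c, amp in zip(range(3), (30.0, 20.0, 10.0)):
            fit = fit_ladder(events[c][0], SR)
            assert fit.t_a_ms == pytest.approx(1.0, abs=dt_ms)
            assert fit.t_s_ms == pytest.approx(3.0, abs=dt_ms)
            assert fit.t_d_ms == pytest.approx(1.0, abs=dt_ms)
            assert fit.i_f_mV == pytest.approx(amp, abs=0.1)


def fit_at(t_s: float) -> LadderFit:
    return LadderFit(t_a_ms=1.0, t_s_ms=2.0, t_d_ms=1.0, i_f_mV=10.0,
                     fit_residual_mV=0.1, t_center_s=t_s)


class TestMatchChannels:
    def test_identical_timestamps_all_matched(self):
        fits = [[fit_at(0.01), fit_at(0.05)] for _ in range(3)]
        result = match_channels(fits, tolerance_ms=1.0)
        assert len(result.matched) == 2
        assert result.n_dropped == 0

    def test_singleton_event_dropped_and_counted(self):
        fits = [[fit_at(0.01), fit_at(0.05)],
                [fit_at(0.01), fit_at(0.05)],
                [fit_at(0.01), fit_at(0.05), fit_at(0.2)]]
        result = match_channels(fits, tolerance_ms=1.0)
        assert len(result.matched) == 2
        assert result.n_dropped == 1

    def test_jittered_timestamps_within_tolerance_matched(self, rng):
        base = np.sort(rng.uniform(0, 1, 30))
        fits = [[fit_at(t + rng.uniform(-2e-4, 2e-4)) for t in base]
                for _ in range(3)]
        result = match_channels(fits, tolerance_ms=1.0)
        assert len(result.matched) == 30
        assert result.n_dropped == 0

    def test_each_fit_used_at_most_once(self):
        fits = [[fit_at(0.01)],
                [fit_at(0.0099), fit_at(0.0101)],
                [fit_at(0.01)]]
        result = match_channels(fits, tolerance_ms=1.0)
        assert len(result.matched) == 1
        assert result.n_dropped == 1
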