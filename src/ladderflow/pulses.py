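"""Pulse processing: median filtering, background statistics, event
detection, ladder (trapezoid) fitting and cross-channel coincidence matching.

The processing chain mirrors how constrictional-microchannel recordings are
reduced: a 50-point median filter suppresses PMT background spikes, the
baseline mean and SD set a ``mean + 3 sigma`` detection threshold, maximal
suprathreshold runs become candidate events, and each event is fitted with a
trapezoid whose rise (``T_a``), plateau (``T_s``), fall (``T_d``) and
above-baseline plateau intensity (``I_f``) are the per-cell features.
Coincident events across the three detector channels are matched into one
cell transit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .simulate import RawTrace

__all__ = [
    "DetectionSettings",
    "PulseEvent",
    "LadderFit",
    "MatchedEvent",
    "MatchResult",
    "BackgroundStats",
    "median_filter",
    "estimate_background",
    "detect_events",
    "fit_ladder",
    "match_channels",
]


@dataclass
class DetectionSettings:
    """Tunables of the detection chain.

    ``median_window`` is bumped to the next odd number internally so the
    filter is centred.  ``threshold_k`` is the SD multiplier of the
    detection threshold.  Events flagged as anomalously long (more than
    ``long_event_factor`` times the median event duration, a doublet
    heuristic) are excluded only if ``exclude_long_events`` is set; by
    default they are kept, because genuinely slow cells in a heavy-tailed
    velocity distribution produce long single-cell pulses.
    """

    median_window: int = 50
    threshold_k: float = 3.0
    min_event_samples: int = 100
    coincidence_tolerance_ms: float = 1.0
    long_event_factor: float = 3.0
    exclude_long_events: bool = False

    def __post_init__(self) -> None:
        if self.median_window < 1:
            raise ValueError("median_window must be >= 1")
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")

    @property
    def effective_median_window(self) -> int:
        w = int(self.median_window)
        return w if w % 2 == 1 else w + 1


@dataclass
class BackgroundStats:
    """Per-channel robust baseline statistics (mV)."""

    mean: np.ndarray
    sd: np.ndarray
    threshold: np.ndarray
    zero_variance: bool = False


@dataclass
class PulseEvent:
    """One suprathreshold excursion on one channel.

    ``start``/``end`` are 0-based, half-open sample indices into the
    (filtered) trace the event was detected on.
    """

    channel: int
    start: int
    end: int
    peak_mV: float
    segment: np.ndarray = field(repr=False)
    flagged_long: bool = False

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class LadderFit:
    """Trapezoid fit of one event: timings in ms, plateau in mV above
    baseline, RMS residual in mV, pulse centre in seconds."""

    t_a_ms: float
    t_s_ms: float
    t_d_ms: float
    i_f_mV: float
    fit_residual_mV: float
    t_center_s: float
    converged: bool = True

    @property
    def total_ms(self) -> float:
        return self.t_a_ms + self.t_s_ms + self.t_d_ms


@dataclass
class MatchedEvent:
    """Per-channel ladder fits of one cell transit (FITC, PE, PerCP)."""

    fits: tuple[LadderFit, LadderFit, LadderFit]
    t_center_s: float

    @property
    def plateaus_mV(self) -> np.ndarray:
        return np.array([f.i_f_mV for f in self.fits])


@dataclass
class MatchResult:
    matched: list[MatchedEvent]
    n_dropped: int


def median_filter(trace: RawTrace, window: int) -> RawTrace:
    """Sliding-window median per channel with replicate (edge) padding.

    Output length equals input length; an even ``window`` is widened by one
    to keep the window centred.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > trace.n_samples:
        raise ValueError(
            f"median window {window} exceeds trace length {trace.n_samples}"
        )
    w = window if window % 2 == 1 else window + 1
    filtered = np.stack([
        ndimage.median_filter(np.ascontiguousarray(trace.values[c]),
                              size=w, mode="nearest")
        for c in range(trace.n_channels)
    ])
    return RawTrace(values=filtered, sample_rate_hz=trace.sample_rate_hz,
                    channel_names=trace.channel_names)


def estimate_background(trace: RawTrace, threshold_k: float = 3.0
                        ) -> BackgroundStats:
    """Two-pass robust baseline statistics per channel.

    The first pass uses outlier-resistant statistics (median and
    MAD-derived sigma) so that pulses, which can occupy a large fraction of
    a busy trace, do not inflate the estimate; the second pass recomputes
    ordinary mean/SD after excluding every suprathreshold excursion in full
    (each run above ``median + k * sigma`` extended outward to the nearest
    median crossing, so pulse rise/fall ramps are excluded too).
    ``threshold = mean + k * sd``.
    """
    vals = trace.values
    med = np.median(vals, axis=1)
    mad_sigma = 1.4826 * np.median(np.abs(vals - med[:, None]), axis=1)
    means = np.empty(vals.shape[0])
    sds = np.empty(vals.shape[0])
    for c in range(vals.shape[0]):
        ch = vals[c]
        keep = np.ones(ch.shape, dtype=bool)
        cutoff = med[c] + threshold_k * mad_sigma[c]
        for start, end in _runs_above(ch > cutoff):
            while start > 0 and ch[start - 1] > med[c]:
                start -= 1
            while end < len(ch) and ch[end] > med[c]:
                end += 1
            keep[start:end] = False
        sub = ch[keep] if keep.any() else ch
        means[c] = sub.mean()
        sds[c] = sub.std()
    zero_var = bool(np.any(sds == 0))
    return BackgroundStats(mean=means, sd=sds,
                           threshold=means + threshold_k * sds,
                           zero_variance=zero_var)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) index pairs of maximal True runs."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def detect_events(trace: RawTrace, settings: DetectionSettings,
                  background: BackgroundStats | None = None
                  ) -> list[list[PulseEvent]]:
    """Detect suprathreshold pulse events on every channel.

    Maximal contiguous runs above ``mean + k*sd`` whose length reaches
    ``min_event_samples`` become events; event boundaries are extended
    outward to the nearest baseline (mean) crossing so the full rise and
    fall are retained for fitting.  Events per channel are ordered by start
    index.  Runs longer than ``long_event_factor`` times the per-channel
    median event duration are flagged (and excluded when
    ``exclude_long_events`` is set).
    """
    if background is None:
        background = estimate_background(trace, settings.threshold_k)
    out: list[list[PulseEvent]] = []
    for c in range(trace.n_channels):
        vals = trace.values[c]
        spans: list[tuple[int, int]] = []
        for start, end in _runs_above(vals > background.threshold[c]):
            if end - start < settings.min_event_samples:
                continue
            # extend to the nearest baseline-mean crossing
            while start > 0 and vals[start - 1] > background.mean[c]:
                start -= 1
            while end < len(vals) and vals[end] > background.mean[c]:
                end += 1
            # a noise dip can split one pulse into two runs that extend to
            # the same support; merge overlapping spans
            if spans and start <= spans[-1][1]:
                spans[-1] = (spans[-1][0], max(spans[-1][1], end))
            else:
                spans.append((start, end))
        events = [
            PulseEvent(channel=c, start=start, end=end,
                       peak_mV=float(vals[start:end].max()),
                       segment=vals[start:end].copy())
            for start, end in spans
        ]
        if events:
            durations = np.array([e.n_samples for e in events], dtype=float)
            limit = settings.long_event_factor * np.median(durations)
            for e in events:
                e.flagged_long = e.n_samples > limit
            if settings.exclude_long_events:
                events = [e for e in events if not e.flagged_long]
        out.append(events)
    return out


def _trapezoid(t: np.ndarray, t0: float, w_a: float, w_s: float,
               w_d: float, amp: float) -> np.ndarray:
    knots = np.array([t0, t0 + w_a, t0 + w_a + w_s, t0 + w_a + w_s + w_d])
    # guard against zero-width segments for np.interp monotonicity
    knots = np.maximum.accumulate(knots + np.arange(4) * 1e-12)
    return amp * np.interp(t, knots, [0.0, 1.0, 1.0, 0.0], left=0.0, right=0.0)


def fit_ladder(event: PulseEvent, sample_rate_hz: float,
               baseline_mV: float = 0.0) -> LadderFit:
    """Least-squares trapezoid ("ladder") fit of one event segment.

    The plateau level is seeded from the upper quartile of the segment and
    the four breakpoints from threshold crossings at 10% / 90% of that
    level; all five parameters are then refined with bounded least squares.
    Times are reported in ms, the plateau in mV above the supplied baseline.
    """
    y = event.segment.astype(float) - baseline_mV
    n = len(y)
    dt_ms = 1e3 / sample_rate_hz
    t = np.arange(n) * dt_ms

    top = y[y >= 0.8 * y.max()]
    amp0 = float(np.median(top)) if len(top) else float(y.max())
    if amp0 <= 0:
        amp0 = max(float(y.max()), 1e-6)
    hi = np.flatnonzero(y >= 0.9 * amp0)
    lo = np.flatnonzero(y >= 0.1 * amp0)
    i_lo0, i_lo1 = (int(lo[0]), int(lo[-1])) if len(lo) else (0, n - 1)
    i_hi0, i_hi1 = (int(hi[0]), int(hi[-1])) if len(hi) else (i_lo0, i_lo1)
    t0 = i_lo0 * dt_ms
    w_a0 = max((i_hi0 - i_lo0) * dt_ms, dt_ms)
    w_s0 = max((i_hi1 - i_hi0) * dt_ms, dt_ms)
    w_d0 = max((i_lo1 - i_hi1) * dt_ms, dt_ms)

    span = (n - 1) * dt_ms

    def residuals(p: np.ndarray) -> np.ndarray:
        return _trapezoid(t, *p) - y

    p0 = np.array([t0, w_a0, w_s0, w_d0, amp0])
    lb = np.array([-span, 0.0, 0.0, 0.0, 0.0])
    ub = np.array([span, 2 * span, 2 * span, 2 * span, np.inf])
    try:
        sol = optimize.least_squares(residuals, p0, bounds=(lb, ub),
                                     method="trf", x_scale="jac")
        p = sol.x
        converged = bool(sol.success)
    except Exception:
        p, converged = p0, False

    t0_f, w_a, w_s, w_d, amp = p
    rms = float(np.sqrt(np.mean(residuals(p) ** 2)))
    center_ms = t0_f + (w_a + w_s + w_d) / 2.0
    t_center_s = event.start / sample_rate_hz + center_ms * 1e-3
    return LadderFit(t_a_ms=float(w_a), t_s_ms=float(w_s), t_d_ms=float(w_d),
                     i_f_mV=float(amp), fit_residual_mV=rms,
                     t_center_s=float(t_center_s), converged=converged)


def match_channels(fits_per_channel: list[list[LadderFit]],
                   tolerance_ms: float = 1.0) -> MatchResult:
    """Greedy nearest-time matching of per-channel fits into cell transits.

    Walking the first channel's fits in time order, the nearest unused fit
    within ``tolerance_ms`` is taken from each other channel; fits that
    cannot complete a triple are dropped and counted.  Each fit is used at
    most once.
    """
    if len(fits_per_channel) != 3:
        raise ValueError("expected fits for exactly 3 channels")
    sorted_fits = [sorted(ch, key=lambda f: f.t_center_s)
                   for ch in fits_per_channel]
    used = [np.zeros(len(ch), dtype=bool) for ch in sorted_fits]
    times = [np.array([f.t_center_s for f in ch]) for ch in sorted_fits]
    tol_s = tolerance_ms * 1e-3

    matched: list[MatchedEvent] = []
    for i, f0 in enumerate(sorted_fits[0]):
        picks = [i]
        ok = True
        for c in (1, 2):
            if len(times[c]) == 0:
                ok = False
                break
            d = np.abs(times[c] - f0.t_center_s)
            d[used[c]] = np.inf
            j = int(np.argmin(d))
            if d[j] > tol_s:
                ok = False
                break
            picks.append(j)
        if not ok:
            continue
        used[0][i] = True
        used[1][picks[1]] = True
        used[2][picks[2]] = True
        fits = (f0, sorted_fits[1][picks[1]], sorted_fits[2][picks[2]])
        matched.append(MatchedEvent(
            fits=fits,
            t_center_s=float(np.mean([f.t_center_s for f in fits])),
        ))
    n_total = sum(len(ch) for ch in sorted_fits)
    return MatchResult(matched=matched, n_dropped=n_total - 3 * len(matched))
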