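"""Wing-beat synchrony analysis of dual-wing reflectance recordings.

The procedure mirrors the tethered-flight assay it was written for: detect
flight bouts (segments where the signal variance rises above the rest
baseline), place a fixed number of short analysis windows (5 ms by
default) uniformly at random inside the bouts, compute the left-right
Pearson correlation r in each window, classify a window as a synchronized
event when r exceeds a strict threshold (0.5 by default), and pool events
across flies into a proportion with an exact binomial confidence interval.
A spectral estimator recovers the wing-beat fundamental, undoing the
frequency doubling that a unimodal proximity-sensor response imposes on a
sinusoidal stroke.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .proportions import clopper_pearson_ci
from .simulate import Recording

__all__ = [
    "FlightBout",
    "SyncEvent",
    "SyncSummary",
    "AnalysisParams",
    "WindowDraw",
    "detect_flight_bouts",
    "sample_windows",
    "window_correlation",
    "classify_event",
    "analyze_recording",
    "summarize_events",
    "estimate_wingbeat_frequency",
]

LABELS = ("synchronized", "unsynchronized", "degenerate")


@dataclass(frozen=True)
class FlightBout:
    """Half-open sample interval [start, end) of sustained wing oscillation."""

    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.start_sample >= self.end_sample:
            raise ValueError("bout start must precede its end")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass(frozen=True)
class SyncEvent:
    """One analysis window with its Pearson r and classification.

    ``r`` is NaN when either channel is constant in the window (a rest or
    clipped segment); such windows carry the ``degenerate`` label and are
    excluded from the synchrony proportion.
    """

    start_sample: int
    window_samples: int
    r: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")


@dataclass(frozen=True)
class SyncSummary:
    """Pooled synchronized-event proportion with exact binomial CI."""

    n_events: int
    n_synchronized: int
    n_degenerate: int
    proportion_synchronized: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95


@dataclass(frozen=True)
class AnalysisParams:
    """Windowing and classification parameters.

    Defaults follow the assay: 5-ms windows, 50 windows per recording,
    synchronized means r strictly greater than 0.5, windows restricted to
    detected flight bouts.
    """

    window_ms: float = 5.0
    n_windows: int = 50
    r_threshold: float = 0.5
    seed: int = 0
    restrict_to_bouts: bool = True

    def window_samples(self, fs_hz: float) -> int:
        w = int(round(self.window_ms * fs_hz / 1000.0))
        if w < 3:
            raise ValueError(
                f"window of {self.window_ms} ms at {fs_hz} Hz holds {w} < 3 samples"
            )
        return w


@dataclass(frozen=True)
class WindowDraw:
    """Window start positions plus a flag when fewer were available than asked."""

    starts: tuple
    n_requested: int
    shortfall: bool


def _rolling_sd(x: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling standard deviation (population), edges truncated."""
    s = pd.Series(x, dtype=float)
    return s.rolling(window, center=True, min_periods=1).std(ddof=0).to_numpy()


def detect_flight_bouts(
    recording: Recording,
    min_bout_ms: float = 50.0,
    k_sigma: float = 4.0,
    rolling_ms: float = 25.0,
) -> list[FlightBout]:
    """Detect flight bouts from signal variance.

    A sample is active when the centred rolling standard deviation
    (``rolling_ms`` window, either channel) exceeds ``k_sigma`` times the
    baseline noise sd, estimated as the mean rolling sd over the
    lowest-variance decile of samples (floored at half an ADC count so a
    noiseless rest segment cannot produce a zero threshold).  Active runs
    shorter than ``min_bout_ms`` are discarded.  Returns sorted,
    non-overlapping bouts.

    A recording without internal variance contrast (continuous flight, or
    rest throughout) offers no rest baseline for this rule, so when the
    upper rolling-sd decile does not exceed ``k_sigma`` times the baseline
    the whole recording is classified at once: it is a single bout when
    its spectrum is narrowband (a dominant oscillation line well above the
    broadband floor), and boutless otherwise.
    """
    n = len(recording)
    window = int(round(rolling_ms * recording.fs_hz / 1000.0))
    if n < window:
        raise ValueError(
            f"recording of {n} samples is shorter than the {window}-sample rolling window"
        )
    sd = np.maximum(_rolling_sd(recording.left, window),
                    _rolling_sd(recording.right, window))
    decile = np.quantile(sd, 0.10)
    baseline = float(np.mean(sd[sd <= decile])) if np.any(sd <= decile) else float(decile)
    baseline = max(baseline, 0.5)  # quantisation-scale floor

    if float(np.quantile(sd, 0.90)) <= k_sigma * baseline:
        # homogeneous recording: all-flight vs all-rest, decided on the
        # quietest slice so sparse transients cannot masquerade as flight
        i = int(np.argmin(sd))
        half = max(window, int(round(0.05 * recording.fs_hz)))
        lo, hi = max(0, i - half), min(n, i + half)
        quiet = Recording(fs_hz=recording.fs_hz, left=recording.left[lo:hi],
                          right=recording.right[lo:hi])
        return [FlightBout(0, n)] if _is_narrowband(quiet) else []
    active = sd > k_sigma * baseline

    min_run = int(round(min_bout_ms * recording.fs_hz / 1000.0))
    bouts = []
    padded = np.concatenate(([False], active, [False]))
    changes = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, end in zip(changes[::2], changes[1::2]):
        if end - start >= min_run:
            bouts.append(FlightBout(int(start), int(end)))
    return bouts


def _is_narrowband(recording: Recording, concentration: float = 50.0) -> bool:
    """True when either channel's spectrum is dominated by one line.

    Sustained wing oscillation concentrates power in a narrow band (the
    doubled beat line), whereas sensor noise at rest is broadband; the
    peak-to-median power ratio of a Welch periodogram separates the two by
    orders of magnitude.
    """
    for channel in (recording.left, recording.right):
        x = np.asarray(channel, dtype=float)
        if np.ptp(x) == 0:
            continue
        nperseg = min(x.size, 4096)
        freqs, power = sps.welch(x, fs=recording.fs_hz, nperseg=nperseg,
                                 detrend="constant")
        power = power[1:]  # drop the DC bin
        med = float(np.median(power))
        if med == 0.0 or float(power.max()) / med > concentration:
            return True
    return False


def sample_windows(
    recording: Recording,
    bouts: Sequence[FlightBout],
    params: AnalysisParams,
) -> WindowDraw:
    """Draw window start positions uniformly without replacement.

    Admissible starts are positions whose full window lies inside one bout
    (or anywhere in the recording when ``params.restrict_to_bouts`` is
    false).  Up to ``params.n_windows`` starts are drawn; if fewer are
    admissible, all are returned and ``shortfall`` is set — a flightless
    recording yields an empty draw rather than an error.  Deterministic
    given ``params.seed``.
    """
    w = params.window_samples(recording.fs_hz)
    if params.restrict_to_bouts:
        admissible = np.concatenate([
            np.arange(b.start_sample, b.end_sample - w + 1)
            for b in bouts if b.n_samples >= w
        ]) if bouts else np.array([], dtype=int)
    else:
        admissible = np.arange(0, len(recording) - w + 1)
    if admissible.size == 0:
        return WindowDraw(starts=(), n_requested=params.n_windows, shortfall=True)
    rng = np.random.default_rng(params.seed)
    k = min(params.n_windows, admissible.size)
    starts = rng.choice(admissible, size=k, replace=False)
    return WindowDraw(
        starts=tuple(int(s) for s in np.sort(starts)),
        n_requested=params.n_windows,
        shortfall=k < params.n_windows,
    )


def window_correlation(left_segment, right_segment) -> float:
    """Pearson product-moment correlation of two window segments.

    Computed on the raw sample values, no detrending.  Returns NaN when
    either segment has zero variance (e.g. a rest or saturated window),
    signalling an undefined correlation.
    """
    x = np.asarray(left_segment, dtype=float)
    y = np.asarray(right_segment, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"segment lengths differ: {x.size} vs {y.size}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("segments must be 1-D with at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float((xc @ yc) / denom)


def classify_event(r: float, r_threshold: float = 0.5) -> str:
    """Label a window: synchronized iff r is defined and strictly exceeds the threshold."""
    if r is None or math.isnan(r):
        return "degenerate"
    return "synchronized" if r > r_threshold else "unsynchronized"


def analyze_recording(
    recording: Recording,
    params: AnalysisParams | None = None,
    bouts: Sequence[FlightBout] | None = None,
    min_bout_ms: float = 50.0,
    k_sigma: float = 4.0,
) -> list[SyncEvent]:
    """Run the full per-recording pipeline: bouts, windows, r, labels."""
    params = params or AnalysisParams()
    if bouts is None and params.restrict_to_bouts:
        bouts = detect_flight_bouts(recording, min_bout_ms=min_bout_ms, k_sigma=k_sigma)
    draw = sample_windows(recording, bouts or [], params)
    w = params.window_samples(recording.fs_hz)
    events = []
    for start in draw.starts:
        r = window_correlation(recording.left[start:start + w],
                               recording.right[start:start + w])
        events.append(SyncEvent(start_sample=start, window_samples=w, r=r,
                                label=classify_event(r, params.r_threshold)))
    return events


def summarize_events(
    events: Iterable[SyncEvent],
    conf_level: float = 0.95,
) -> SyncSummary:
    """Pool events (across flies) into a synchronized-event proportion.

    The proportion is taken over non-degenerate events; its confidence
    interval is the exact binomial (Clopper-Pearson) interval.  Raises
    ``ValueError`` when every event is degenerate.
    """
    events = list(events)
    n_events = len(events)
    n_deg = sum(e.label == "degenerate" for e in events)
    n_sync = sum(e.label == "synchronized" for e in events)
    n_valid = n_events - n_deg
    if n_valid == 0:
        raise ValueError("no non-degenerate events to summarize")
    ci = clopper_pearson_ci(n_sync, n_valid, conf_level)
    return SyncSummary(
        n_events=n_events,
        n_synchronized=n_sync,
        n_degenerate=n_deg,
        proportion_synchronized=n_sync / n_valid,
        ci_low=ci.ci_low,
        ci_high=ci.ci_high,
        conf_level=conf_level,
    )


def estimate_wingbeat_frequency(
    recording: Recording,
    bouts: Sequence[FlightBout],
    subharmonic_fraction: float = 0.10,
    max_beat_hz: float = 300.0,
    min_freq_hz: float = 20.0,
) -> float:
    """Estimate the wing-beat fundamental frequency in Hz.

    A unimodal sensor response makes the stroke sweep through the
    peak-response distance twice per beat, so the dominant spectral line
    sits at twice the beat frequency whenever the stroke straddles the
    peak.  Per channel, the estimator takes the Welch periodogram of the
    longest bout, finds the peak ``f*`` above ``min_freq_hz``, and

    1. reports ``f*/2`` when the spectrum holds at least
       ``subharmonic_fraction`` of the peak power at ``f*/2`` (the
       fundamental is visible and ``f*`` is its doubled line);
    2. otherwise halves ``f*`` until it falls at or below ``max_beat_hz``
       (a perfectly symmetric stroke leaves no power at the fundamental,
       so doubling is undone by the physiological-band convention).

    The two per-channel estimates are averaged.  Raises ``ValueError``
    when there are no bouts, the signal is flat, or the bout is shorter
    than 20 periods of the candidate frequency.
    """
    if not bouts:
        raise ValueError("no flight bouts: cannot estimate a wing-beat frequency")
    longest = max(bouts, key=lambda b: b.n_samples)
    fs = recording.fs_hz
    estimates = []
    for channel in (recording.left, recording.right):
        seg = np.asarray(channel[longest.start_sample:longest.end_sample], dtype=float)
        if np.ptp(seg) == 0:
            raise ValueError("flat signal within the bout: no oscillation to measure")
        nperseg = min(len(seg), 8192)
        freqs, power = sps.welch(seg, fs=fs, nperseg=nperseg, detrend="constant")
        band = freqs >= min_freq_hz
        if not np.any(band) or np.all(power[band] == 0):
            raise ValueError("no spectral power above the minimum frequency")
        idx = np.flatnonzero(band)[np.argmax(power[band])]
        f_peak = float(freqs[idx])
        peak_power = float(power[idx])
        if longest.n_samples / fs < 20.0 / max(f_peak, min_freq_hz):
            raise ValueError("longest bout holds fewer than 20 beat periods")
        df = freqs[1] - freqs[0]
        near_half = np.abs(freqs - f_peak / 2.0) <= 2 * df
        half_power = float(power[near_half].max()) if np.any(near_half) else 0.0
        if half_power >= subharmonic_fraction * peak_power:
            f_beat = f_peak / 2.0
        else:
            f_beat = f_peak
            while f_beat > max_beat_hz:
                f_beat /= 2.0
        estimates.append(f_beat)
    return float(np.mean(estimates))
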