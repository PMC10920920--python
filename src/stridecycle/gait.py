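"""Gait-cycle extraction from head-position traces.

During natural walking the vertical position of the head oscillates with one
trough per footfall (double support) and one peak per swing phase.  Detecting
those troughs in the 90 Hz head-height time series yields the footfall times
from which strides (two sequential steps, trough-to-trough-to-trough) are
epoched.  Each stride is resampled onto a normalized 200-point phase grid
(0.5-100% cycle completion in 0.5% steps) so that strides of different
durations can be pooled and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

#: Normalized stride-phase grid: 0.5, 1.0, ..., 100.0 percent (200 points).
PHASE_GRID = np.arange(1, 201) * 0.5

DEFAULT_MIN_PROMINENCE_FRAC = 0.25
DEFAULT_MIN_SEPARATION_S = 0.35


@dataclass
class HeadTrace:
    """Per-trial vertical head-position samples on a uniform time grid."""

    participant_id: str
    trial_id: int
    t: np.ndarray  # seconds, trial-relative, strictly increasing
    height: np.ndarray  # metres, vertical head position

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.height.shape:
            raise ValueError("t and height must be 1-D arrays of equal length")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def frame_interval(self) -> float:
        """Median inter-sample interval (robust to drop-out gaps)."""
        if self.t.size < 2:
            raise ValueError("need at least 2 samples")
        return float(np.median(np.diff(self.t)))


@dataclass
class StrideEpoch:
    """One stride: two sequential steps spanning three footfall troughs."""

    participant_id: str
    trial_id: int
    trough_times: tuple[float, float, float]  # start, mid, end (seconds)
    normalized_height: np.ndarray | None = field(default=None, repr=False)

    @property
    def start_s(self) -> float:
        return self.trough_times[0]

    @property
    def mid_s(self) -> float:
        return self.trough_times[1]

    @property
    def end_s(self) -> float:
        return self.trough_times[2]

    @property
    def duration_s(self) -> float:
        return self.trough_times[2] - self.trough_times[0]

    def step_durations(self) -> tuple[float, float]:
        t0, t1, t2 = self.trough_times
        return (t1 - t0, t2 - t1)


@dataclass
class QCBounds:
    """Trial-exclusion thresholds for the gait quality check."""

    max_gap_frames: float = 3.0       # drop-out: gap > this many frame intervals
    min_height_range: float = 0.005   # metres; flat-signal floor (5-95 pctl range)
    step_duration_bounds: tuple[float, float] = (0.35, 1.0)  # seconds
    min_troughs: int = 3


@dataclass
class QCResult:
    accepted: bool
    reasons: list[str]


def detrend_height(trace: HeadTrace) -> HeadTrace:
    """Remove the least-squares line from the height signal.

    Slow drift in head height (e.g. posture change along the walkway) biases
    trough prominence, so traces are detrended before peak detection.  The
    output has zero mean by construction.
    """
    if trace.t.size < 2:
        raise ValueError("detrend requires at least 2 samples")
    coef = np.polyfit(trace.t, trace.height, 1)
    resid = trace.height - np.polyval(coef, trace.t)
    return HeadTrace(trace.participant_id, trace.trial_id, trace.t.copy(), resid)


DEFAULT_LOWPASS_HZ = 4.0


def detect_troughs(
    trace: HeadTrace,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    lowpass_hz: float | None = DEFAULT_LOWPASS_HZ,
) -> np.ndarray:
    """Find footfall troughs (local minima of head height).

    The signal is first low-pass filtered (zero-phase Butterworth, default
    4 Hz cutoff - comfortably above the ~1.7 Hz step rate) so sensor noise
    does not displace the minima; pass ``lowpass_hz=None`` to disable.
    Prominence is thresholded at ``min_prominence_frac`` times the 5-95
    percentile height range of the trial, and minima closer together than
    ``min_separation_s`` (default below the fastest plausible step) are
    suppressed.  Returns sample indices in time order; an empty array means
    the trial will fail QC downstream.
    """
    if trace.t.size < 3:
        return np.array([], dtype=int)
    height = trace.height
    if lowpass_hz is not None and trace.t.size > 15:
        fs = 1.0 / trace.frame_interval()
        if lowpass_hz < fs / 2:
            sos = butter(2, lowpass_hz, fs=fs, output="sos")
            height = sosfiltfilt(sos, height)
    lo, hi = np.percentile(height, [5, 95])
    height_range = hi - lo
    if height_range <= 1e-9:
        return np.array([], dtype=int)
    distance = max(1, int(round(min_separation_s / trace.frame_interval())))
    idx, _ = find_peaks(
        -height,
        prominence=min_prominence_frac * height_range,
        distance=distance,
    )
    # The zero-phase filter can displace a minimum by a sample or two when
    # neighbouring arcs are asymmetric.  If the raw signal is effectively
    # noiseless (tiny high-frequency residual), snap each trough to the raw
    # local minimum; under real noise the raw argmin jitters more than the
    # filtered one, so leave it alone.
    if height is not trace.height and idx.size:
        residual_sd = float(np.std(trace.height - height))
        if residual_sd < 0.02 * height_range:
            refined = []
            for i in idx:
                a, b = max(0, i - 3), min(trace.height.size, i + 4)
                refined.append(a + int(np.argmin(trace.height[a:b])))
            idx = np.unique(refined)
    return idx


def epoch_strides(
    troughs: np.ndarray | Sequence[int],
    trace: HeadTrace,
    mode: Literal["overlap", "tile"] = "overlap",
    resample: bool = False,
) -> list[StrideEpoch]:
    """Epoch strides from consecutive trough triples.

    ``overlap`` advances by one trough per stride (maximal stride coverage for
    curve averaging); ``tile`` advances by two (non-overlapping strides, the
    partition used for event phase assignment).  Fewer than three troughs
    yields no strides.
    """
    idx = np.asarray(troughs, dtype=int)
    if idx.size < 3:
        return []
    times = trace.t[idx]
    step = 1 if mode == "overlap" else 2
    epochs = []
    for i in range(0, idx.size - 2, step):
        ep = StrideEpoch(
            trace.participant_id,
            trace.trial_id,
            (float(times[i]), float(times[i + 1]), float(times[i + 2])),
        )
        if resample:
            try:
                ep.normalized_height = resample_stride(ep, trace)
            except ValueError:
                continue  # too few raw samples: stride rejected
        epochs.append(ep)
    return epochs


def resample_stride(epoch: StrideEpoch, trace: HeadTrace) -> np.ndarray:
    """Linearly interpolate one stride onto the 200-point phase grid.

    Phase p% maps to time ``start + p/100 * duration``; the grid spans
    (start, end] so the first point sits at 0.5% and the last exactly at the
    closing trough.  With 90 Hz sampling and steps of at least 0.35 s every
    step contributes over 30 raw samples, so linear interpolation is ample.
    """
    n_raw = int(np.sum((trace.t >= epoch.start_s) & (trace.t <= epoch.end_s)))
    if n_raw < 4:
        raise ValueError("stride spans fewer than 4 raw samples")
    target_t = epoch.start_s + PHASE_GRID / 100.0 * epoch.duration_s
    return np.interp(target_t, trace.t, trace.height)


def qc_trials(
    trace: HeadTrace,
    troughs: np.ndarray | Sequence[int],
    bounds: QCBounds | None = None,
) -> QCResult:
    """Classify a trial as usable or excluded, with reasons.

    Rejection rules: (a) wireless drop-out (any inter-sample gap exceeding
    ``max_gap_frames`` frame intervals), (b) flat signal (5-95 percentile
    height range below floor), (c) implausible gait (median step duration
    outside the configured bounds), (d) too few troughs to form a stride.
    """
    bounds = bounds or QCBounds()
    reasons: list[str] = []
    idx = np.asarray(troughs, dtype=int)

    if trace.t.size >= 2:
        dt = np.diff(trace.t)
        if np.any(dt > bounds.max_gap_frames * trace.frame_interval()):
            reasons.append("drop-out")
    lo, hi = (np.percentile(trace.height, [5, 95])
              if trace.t.size else (0.0, 0.0))
    if hi - lo < bounds.min_height_range:
        reasons.append("flat-signal")
    if idx.size < bounds.min_troughs:
        reasons.append("too-few-troughs")
    else:
        steps = np.diff(trace.t[idx])
        med = float(np.median(steps))
        lo_s, hi_s = bounds.step_duration_bounds
        if not (lo_s <= med <= hi_s):
            reasons.append("implausible-step-duration")
    return QCResult(accepted=not reasons, reasons=reasons)
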