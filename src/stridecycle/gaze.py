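"""Gaze-trace quality control: blink repair, off-gaze target exclusion, and
the pupil-origin mechanical-artefact control.

Blinks appear in headset eye-tracking streams as large discontinuities in
the recorded gaze-direction coordinates; they are detected as per-axis
frame-to-frame jumps beyond a threshold (0.8 m on the recorded coordinate
stream), merged when close in time, and repaired with a modified Akima
(makima) piecewise-cubic interpolation over a padded window.  Target events
presented while gaze was far from the target (beyond a visual-angle limit)
are excluded.  The pupil-origin control asks whether gaze-origin coordinate
variability is itself modulated by stride phase, which would flag a
mechanical rather than perceptual origin of performance oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import Akima1DInterpolator

from .projection import BinnedSeries, bin_centers, bin_index, phase_from_troughs

DEFAULT_JUMP_THRESHOLD_M = 0.8
# Entry and exit jumps of one blink are separated by the blink's duration,
# so the merge window must cover typical blinks (up to ~350 ms).
DEFAULT_MERGE_WINDOW_S = 0.35
DEFAULT_PAD_S = 0.2
DEFAULT_GAZE_LIMIT_DEG = 12.1


@dataclass
class BlinkInterval:
    start_s: float
    end_s: float


def detect_blinks(
    t: np.ndarray,
    direction: np.ndarray,
    jump_threshold: float = DEFAULT_JUMP_THRESHOLD_M,
    merge_window_s: float = DEFAULT_MERGE_WINDOW_S,
) -> list[BlinkInterval]:
    """Detect blink intervals from gaze-direction discontinuities.

    A frame whose coordinate jump from the previous frame exceeds the
    threshold on any axis seeds an interval; seeds closer together than the
    merge window are joined (a blink produces one jump entering and one
    leaving the artefact).
    """
    t = np.asarray(t, dtype=float)
    d = np.atleast_2d(np.asarray(direction, dtype=float).T).T
    if t.size < 2:
        return []
    jumps = np.abs(np.diff(d, axis=0))
    seed = np.where(np.any(jumps > jump_threshold, axis=1))[0] + 1
    if seed.size == 0:
        return []
    intervals: list[BlinkInterval] = []
    start = prev = seed[0]
    for s in seed[1:]:
        if t[s] - t[prev] <= merge_window_s:
            prev = s
        else:
            intervals.append(BlinkInterval(float(t[start]), float(t[prev])))
            start = prev = s
    intervals.append(BlinkInterval(float(t[start]), float(t[prev])))
    return intervals


def interpolate_blinks(
    t: np.ndarray,
    signal: np.ndarray,
    intervals: list[BlinkInterval],
    pad_s: float = DEFAULT_PAD_S,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Repair blink spans with modified-Akima interpolation.

    Samples within ``pad_s`` of any interval are replaced by a makima fit
    through the remaining valid samples, column by column; overlapping
    padded windows merge naturally.  Spans touching the trace edge fall back
    to nearest-valid extrapolation and are flagged.  Returns (repaired
    signal, repaired-sample mask, flags); samples outside padded windows are
    returned bit-identical.
    """
    t = np.asarray(t, dtype=float)
    sig = np.array(signal, dtype=float, copy=True)
    one_d = sig.ndim == 1
    if one_d:
        sig = sig[:, None]
    bad = np.zeros(t.size, dtype=bool)
    for iv in intervals:
        bad |= (t >= iv.start_s - pad_s) & (t <= iv.end_s + pad_s)
    flags: list[str] = []
    if bad.any() and not bad.all():
        valid = ~bad
        for j in range(sig.shape[1]):
            interp = Akima1DInterpolator(t[valid], sig[valid, j],
                                         method="makima", extrapolate=False)
            repaired = interp(t[bad])
            edge = np.isnan(repaired)
            if edge.any():
                if "edge-extrapolation" not in flags:
                    flags.append("edge-extrapolation")
                before = t[bad][edge] < t[valid][0]
                repaired[edge] = np.where(before, sig[valid, j][0],
                                          sig[valid, j][-1])
            sig[bad, j] = repaired
    elif bad.all():
        flags.append("entire-trace-flagged")
    return (sig[:, 0] if one_d else sig), bad, flags


def angular_offset_deg(gaze_dir: np.ndarray, target_dir: np.ndarray) -> np.ndarray:
    """Angle (degrees) between gaze and target direction vectors from the eye."""
    g = np.atleast_2d(np.asarray(gaze_dir, dtype=float))
    v = np.atleast_2d(np.asarray(target_dir, dtype=float))
    dot = np.sum(g * v, axis=1)
    norms = np.linalg.norm(g, axis=1) * np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(dot / norms, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def exclude_offtarget_events(
    gaze_dir_at_onset: np.ndarray,
    target_dir: np.ndarray,
    limit_deg: float = DEFAULT_GAZE_LIMIT_DEG,
) -> tuple[np.ndarray, list[str]]:
    """Keep/drop flags for target events by gaze-to-target angle.

    Events with angular offset beyond the limit are dropped; events whose
    gaze sample is missing (NaN from an unrepaired blink) are dropped with a
    distinct reason.  Returns (keep mask, per-event reasons).
    """
    offsets = angular_offset_deg(gaze_dir_at_onset, target_dir)
    missing = np.isnan(offsets)
    keep = ~missing & (offsets <= limit_deg)
    reasons = []
    for miss, k in zip(missing, keep):
        if miss:
            reasons.append("missing-gaze")
        elif not k:
            reasons.append("off-gaze")
        else:
            reasons.append("")
    return keep, reasons


def gaze_origin_variability_by_phase(
    t: np.ndarray,
    origin: np.ndarray,
    troughs: np.ndarray,
    n_bins: int = 40,
) -> BinnedSeries:
    """Per-phase-bin dispersion of detrended gaze-origin coordinates.

    Each sample is assigned a stride phase; each origin coordinate is
    linearly detrended over the trial and the pooled standard deviation of
    the residuals is computed per phase bin.  Phase-locked elevation of this
    dispersion (e.g. at footfall) would indicate a mechanical tracking
    artefact; phase-independent noise gives a flat profile.
    """
    t = np.asarray(t, dtype=float)
    origin = np.atleast_2d(np.asarray(origin, dtype=float).T).T
    troughs = np.asarray(troughs, dtype=float)
    if troughs.size < 3:
        raise ValueError("need at least one complete stride")
    phase, _ = phase_from_troughs(t, troughs)
    kept = ~np.isnan(phase)
    if not kept.any():
        raise ValueError("no samples fall inside a stride")
    idx = bin_index(phase[kept], n_bins)

    resid = np.empty_like(origin)
    for j in range(origin.shape[1]):
        coef = np.polyfit(t, origin[:, j], 1)
        resid[:, j] = origin[:, j] - np.polyval(coef, t)
    resid = resid[kept]

    sd = np.full(n_bins, np.nan)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    for b in range(n_bins):
        sel = resid[idx == b].ravel()
        if sel.size >= 2:
            sd[b] = float(np.std(sel, ddof=1))
    return BinnedSeries(measure="gaze_origin_sd", n_bins=n_bins,
                        bin_centers=bin_centers(n_bins), values=sd,
                        counts=counts, statistic="mean")
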