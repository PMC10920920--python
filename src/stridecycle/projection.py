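"""Projection of behavioural events onto normalized stride phase.

Each target onset (or manual response onset) is assigned the percentile of
the stride cycle at which it occurred (phase in (0, 100]), then performance
measures are averaged within linearly spaced phase bins: accuracy (hit rate),
reaction time (hits only), response-onset likelihood and target-presentation
density.  A clock-time control folds the same events into consecutive 1 s
epochs instead of strides, to check that modulations are locked to gait
phase rather than elapsed time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .gait import StrideEpoch

Statistic = Literal["mean", "density"]


@dataclass
class PhaseAssignments:
    """Stride-phase percentiles for a set of events.

    ``phase_pct`` is NaN for dropped events (before the first footfall,
    after the last complete stride); ``stride_idx`` indexes the stride
    tiling, -1 for dropped events.
    """

    onsets: np.ndarray
    phase_pct: np.ndarray        # in (0, 100], NaN if dropped
    stride_idx: np.ndarray       # int, -1 if dropped
    n_dropped: int

    @property
    def kept(self) -> np.ndarray:
        return ~np.isnan(self.phase_pct)


@dataclass
class BinnedSeries:
    """A performance measure averaged within linearly spaced phase bins."""

    measure: str
    n_bins: int
    bin_centers: np.ndarray      # percent
    values: np.ndarray           # NaN where bin empty (mean statistics)
    counts: np.ndarray           # events per bin
    statistic: Statistic = "mean"

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def x(self) -> np.ndarray:
        """Bin centers as stride fraction in (0, 1] (Fourier-model abscissa)."""
        return self.bin_centers / 100.0


def troughs_from_strides(
    strides: Sequence[StrideEpoch] | np.ndarray,
) -> np.ndarray:
    """Unique sorted footfall times underlying a stride set (or pass-through)."""
    if isinstance(strides, np.ndarray):
        return np.asarray(strides, dtype=float)
    times: set[float] = set()
    for ep in strides:
        times.update(ep.trough_times)
    return np.array(sorted(times))


def phase_from_troughs(
    times: np.ndarray,
    troughs: np.ndarray,
    extrapolate: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Stride-phase percentile of each time point given footfall times.

    Strides tile the trial from the first trough (troughs 0-2, 2-4, ...);
    each time in (stride start, stride end] receives phase
    ``100 * (t - start) / (end - start)``, so a footfall instant closing a
    stride gets phase 100 of that stride.  Times outside every complete
    stride get NaN unless ``extrapolate``, in which case the trough sequence
    is padded by one stride of matching duration at each end (used only by
    the synthetic generator to give edge events a well-defined true phase).

    Returns (phase_pct, stride_idx).
    """
    times = np.asarray(times, dtype=float)
    troughs = np.asarray(troughs, dtype=float)
    if extrapolate and troughs.size >= 3:
        pre = troughs[0] - (troughs[2] - troughs[0])
        pre_mid = troughs[0] - (troughs[2] - troughs[1])
        post = troughs[-1] + (troughs[-1] - troughs[-3])
        post_mid = troughs[-1] + (troughs[-1] - troughs[-2])
        troughs = np.concatenate([[pre, pre_mid], troughs, [post_mid, post]])

    phase = np.full(times.shape, np.nan)
    stride_idx = np.full(times.shape, -1, dtype=int)
    if troughs.size < 3:
        return phase, stride_idx
    n_strides = (troughs.size - 1) // 2
    # index of last trough strictly before each time
    j = np.searchsorted(troughs, times, side="left") - 1
    s = j // 2
    ok = (j >= 0) & (s < n_strides)
    start = troughs[2 * s[ok]]
    end = troughs[2 * s[ok] + 2]
    phase[ok] = 100.0 * (times[ok] - start) / (end - start)
    stride_idx[ok] = s[ok]
    return phase, stride_idx


def assign_stride_phase(
    onsets: np.ndarray,
    strides: Sequence[StrideEpoch] | np.ndarray,
) -> PhaseAssignments:
    """Assign each event a stride-phase percentile in (0, 100].

    ``strides`` may be a stride-epoch list or a raw array of footfall times.
    Events falling outside every complete stride are dropped (NaN) and
    counted, so conservation can be audited downstream.
    """
    onsets = np.asarray(onsets, dtype=float)
    troughs = troughs_from_strides(strides)
    phase, stride_idx = phase_from_troughs(onsets, troughs)
    return PhaseAssignments(
        onsets=onsets,
        phase_pct=phase,
        stride_idx=stride_idx,
        n_dropped=int(np.isnan(phase).sum()),
    )


def bin_index(phase_pct: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin index for phases in (0, 100] under half-open (lo, hi] bins."""
    width = 100.0 / n_bins
    idx = np.ceil(np.asarray(phase_pct) / width - 1e-9).astype(int) - 1
    return np.clip(idx, 0, n_bins - 1)


def bin_centers(n_bins: int) -> np.ndarray:
    width = 100.0 / n_bins
    return (np.arange(n_bins) + 0.5) * width


def bin_series(
    phase_pct: np.ndarray,
    values: np.ndarray | None,
    n_bins: int = 40,
    statistic: Statistic = "mean",
    measure: str = "",
) -> BinnedSeries:
    """Average event values within linearly spaced phase bins.

    ``statistic='mean'`` gives the per-bin mean of ``values`` (hit in {0,1}
    for accuracy, reaction time over hits for RT); empty bins become NaN and
    are excluded from downstream Fourier fits.  ``statistic='density'``
    ignores ``values`` and returns per-bin counts normalized to mean 1
    (target or response density).
    """
    phase_pct = np.asarray(phase_pct, dtype=float)
    kept = ~np.isnan(phase_pct)
    idx = bin_index(phase_pct[kept], n_bins)
    counts = np.bincount(idx, minlength=n_bins).astype(float)

    if statistic == "density":
        mean_count = counts.mean()
        vals = counts / mean_count if mean_count > 0 else np.full(n_bins, np.nan)
    elif statistic == "mean":
        if values is None:
            raise ValueError("mean statistic requires values")
        v = np.asarray(values, dtype=float)[kept]
        sums = np.bincount(idx, weights=v, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown statistic {statistic!r}")

    return BinnedSeries(
        measure=measure or statistic,
        n_bins=n_bins,
        bin_centers=bin_centers(n_bins),
        values=vals,
        counts=counts,
        statistic=statistic,
    )


def response_likelihood_series(
    response_onsets: np.ndarray,
    strides: Sequence[StrideEpoch] | np.ndarray,
    n_bins: int = 40,
) -> BinnedSeries:
    """Response-onset likelihood by stride phase.

    The phase-binned density of manual response onsets (not target onsets),
    normalized to mean 1.  Captures when in the stride cycle participants
    actually press, regardless of when the eliciting target appeared.
    """
    asg = assign_stride_phase(np.asarray(response_onsets, dtype=float), strides)
    return bin_series(asg.phase_pct, None, n_bins, "density",
                      measure="response_likelihood")


def target_answered_series(
    target_phase_pct: np.ndarray,
    hit: np.ndarray,
    n_bins: int = 40,
) -> BinnedSeries:
    """Alternative target-locked response measure: fraction answered by
    target phase (selected behind a flag in the pipeline)."""
    return bin_series(target_phase_pct, np.asarray(hit, dtype=float), n_bins,
                      "mean", measure="response_likelihood_target_locked")


def clocktime_series(
    onsets: np.ndarray,
    values: np.ndarray | None = None,
    epoch_length_s: float = 1.0,
    n_bins: int = 40,
    statistic: Statistic = "mean",
    measure: str = "",
) -> BinnedSeries:
    """Control series: events folded into consecutive clock-time epochs.

    Trial-relative onsets are folded modulo ``epoch_length_s`` and binned
    exactly as stride phases are, giving a time-locked (rather than
    gait-locked) performance series.  If rhythmic modulation rides on the
    stride, its fit strength here should collapse once stride durations vary.
    """
    onsets = np.asarray(onsets, dtype=float)
    frac = np.mod(onsets, epoch_length_s) / epoch_length_s
    pseudo_pct = 100.0 * frac
    pseudo_pct[pseudo_pct == 0.0] = 100.0  # fold boundary into (0, 100]
    return bin_series(pseudo_pct, values, n_bins, statistic,
                      measure=measure or "clocktime")
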