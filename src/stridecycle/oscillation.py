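"""Rhythmic-modulation analysis of stride-phase performance series.

The model is a first-order Fourier series at a fixed frequency ``w`` in
cycles per stride (cps), fitted to a phase-binned series y(x) with x the
stride fraction in (0, 1]:

    f(x) = a0 + a1*cos(2*pi*w*x) + b1*sin(2*pi*w*x) = a0 + A*cos(2*pi*w*x + phi)

with amplitude A = sqrt(a1^2 + b1^2) and phase phi = atan2(-b1, a1).  For a
fixed frequency this is an ordinary linear least-squares problem, so the fit
is computed exactly rather than by iterative optimization.  Goodness of fit
(R^2) is swept over a forced grid of 0.2-10 cps in 0.2 steps; statistical
evaluation shuffles outcomes across events within participant to build a
permutation null, retaining the maximum R^2 across all frequencies per
permutation (family-wise control over the frequency grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .projection import BinnedSeries, Statistic, bin_index, bin_series

#: Forced frequency grid: 0.2 to 10 cycles per stride in 0.2 steps.
FREQ_GRID = np.round(np.arange(1, 51) * 0.2, 10)

#: Participant-level frequency bands (cps).
TWO_CPS_BAND = (1.5, 2.5)
FOUR_CPS_BAND = (3.5, 4.5)
HIGH_BAND_MIN = 5.0

Band = Literal["two_cps", "four_cps", "high", "none"]


@dataclass
class FourierFit:
    """Least-squares first-order Fourier fit at one fixed frequency."""

    w: float        # cycles per stride
    a0: float
    a1: float
    b1: float
    amplitude: float
    phi: float      # radians; model = a0 + amplitude*cos(2*pi*w*x + phi)
    r2: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (self.a0 + self.a1 * np.cos(2 * np.pi * self.w * x)
                + self.b1 * np.sin(2 * np.pi * self.w * x))


@dataclass
class SweepResult:
    grid: np.ndarray
    r2_by_freq: np.ndarray
    best_freq: float
    best_fit: FourierFit

    def r2_at(self, w: float) -> float:
        i = int(np.argmin(np.abs(self.grid - w)))
        return float(self.r2_by_freq[i])


@dataclass
class PermutationNull:
    """Null distribution of sweep R^2 from outcome shuffling."""

    n_perm: int
    grid: np.ndarray
    null_r2: np.ndarray           # (n_perm, n_freq)
    maxstat: np.ndarray           # (n_perm,) row maxima
    crit95: float                 # 95th percentile of maxstat
    level: str = "group"

    def critical(self, alpha: float = 0.05) -> float:
        """Conservative (1-alpha) null quantile: the next order statistic at
        or above the nominal rank, so the strict-exceedance test keeps its
        family-wise error at or below alpha at finite n_perm."""
        return float(np.percentile(self.maxstat, 100 * (1 - alpha),
                                   method="higher"))

    def per_freq_critical(self, alpha: float = 0.05) -> np.ndarray:
        return np.percentile(self.null_r2, 100 * (1 - alpha), axis=0,
                             method="higher")


@dataclass
class ParticipantResult:
    participant_id: str
    measure: str
    best_freq: float
    best_r2: float
    significant: bool
    band: Band


@dataclass
class ParticipantEvents:
    """Event-level data for one participant, the unit of permutation."""

    phase_pct: np.ndarray                 # stride-phase percentile per event
    values: np.ndarray | None = None      # outcome per event; None for density


def _design(x: np.ndarray, w: float) -> np.ndarray:
    arg = 2 * np.pi * w * x
    return np.column_stack([np.ones_like(x), np.cos(arg), np.sin(arg)])


def fit_fixed_frequency(series: BinnedSeries | tuple, w: float) -> FourierFit:
    """Exact OLS fit of the fixed-frequency cosine model to a binned series.

    Missing (NaN) bins are dropped rather than imputed.  R^2 is defined as 0
    for a constant series (zero total sum of squares).  A rank-deficient
    design (frequency resonant with the bin spacing) raises ``ValueError``.
    """
    if w <= 0:
        raise ValueError("frequency must be positive")
    if isinstance(series, BinnedSeries):
        x, y = series.x, series.values
    else:
        x, y = series
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need at least 4 non-missing bins")
    X = _design(x, w)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValueError(f"rank-deficient design at w={w} cps")
    a0, a1, b1 = (float(b) for b in beta)
    resid = y - X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
    amp = float(np.hypot(a1, b1))
    phi = float(np.arctan2(-b1, a1))
    return FourierFit(w=float(w), a0=a0, a1=a1, b1=b1,
                      amplitude=amp, phi=phi, r2=r2)


def r2_matrix(Y: np.ndarray, x: np.ndarray,
              grid: np.ndarray = FREQ_GRID) -> np.ndarray:
    """R^2 of the fixed-frequency fit for many series at once.

    ``Y`` is (n_series, n_bins) with a common abscissa ``x``; columns that
    are NaN in any row must be pre-dropped (the permutation machinery
    guarantees a fixed missing-bin pattern).  Returns (n_series, n_freq).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    x = np.asarray(x, dtype=float)
    out = np.empty((Y.shape[0], grid.size))
    sst = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    safe_sst = np.where(sst > 0, sst, 1.0)
    for i, w in enumerate(grid):
        X = _design(x, w)
        beta, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
        ssr = np.sum((Y.T - X @ beta) ** 2, axis=0)
        out[:, i] = np.where(sst > 0, 1.0 - ssr / safe_sst, 0.0)
    return out


def sweep(series: BinnedSeries | tuple,
          grid: np.ndarray = FREQ_GRID) -> SweepResult:
    """Fit the Fourier model at every grid frequency; retain R^2 per
    frequency and the best-fitting frequency (ties break toward the lowest)."""
    r2 = np.full(grid.size, np.nan)
    fits: dict[int, FourierFit] = {}
    for i, w in enumerate(grid):
        try:
            f = fit_fixed_frequency(series, w)
        except ValueError:
            continue
        fits[i] = f
        r2[i] = f.r2
    if not fits:
        raise ValueError("no frequency could be fitted")
    best_i = int(np.nanargmax(r2))
    return SweepResult(grid=grid, r2_by_freq=r2,
                       best_freq=float(grid[best_i]), best_fit=fits[best_i])


def _binned_matrix_null(
    part: ParticipantEvents,
    n_bins: int,
    statistic: Statistic,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant (n_perm, n_bins) matrix of shuffled binned series.

    Mean statistics shuffle outcome values across events with phase labels
    fixed (equivalent to shuffling the events' bin allocation); density
    statistics permute the per-bin counts across bin positions.  Returns
    (matrix, counts); bins empty in the observed data stay empty (NaN) in
    every permutation.
    """
    kept = ~np.isnan(part.phase_pct)
    if statistic == "density":
        counts = np.bincount(bin_index(part.phase_pct[kept], n_bins),
                             minlength=n_bins).astype(float)
        perm_cols = rng.permuted(
            np.tile(np.arange(n_bins), (n_perm, 1)), axis=1)
        mat = counts[perm_cols]
        mean_count = counts.mean()
        mat = mat / mean_count if mean_count > 0 else np.full_like(mat, np.nan)
        return mat, counts

    vals = np.asarray(part.values, dtype=float)[kept]
    idx = bin_index(part.phase_pct[kept], n_bins)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    onehot = np.zeros((vals.size, n_bins))
    onehot[np.arange(vals.size), idx] = 1.0
    perm_idx = rng.permuted(
        np.tile(np.arange(vals.size), (n_perm, 1)), axis=1)
    sums = vals[perm_idx] @ onehot
    with np.errstate(invalid="ignore"):
        mat = np.where(counts > 0, sums / np.maximum(counts, 1.0), np.nan)
    return mat, counts


def permutation_null(
    participants: Sequence[ParticipantEvents],
    n_bins: int = 40,
    statistic: Statistic = "mean",
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    level: str = "group",
    grid: np.ndarray = FREQ_GRID,
) -> PermutationNull:
    """Build the max-statistic permutation null for the frequency sweep.

    Outcomes are shuffled without replacement within each participant, the
    series is rebinned and (for the group level) averaged across
    participants with equal weight, the sweep is re-run, and the maximum
    R^2 across the frequency grid is retained per permutation.  ``crit95``
    is the 95th percentile of those maxima.  The observed data never enter
    the null.
    """
    if n_perm < 100:
        import warnings
        warnings.warn("n_perm < 100 gives an unstable null tail",
                      stacklevel=2)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    acc = np.zeros((n_perm, n_bins))
    nonmissing = np.zeros(n_bins)
    for part in participants:
        mat, counts = _binned_matrix_null(part, n_bins, statistic,
                                          n_perm, rng)
        present = counts > 0 if statistic == "mean" else np.full(n_bins, True)
        acc[:, present] += mat[:, present]
        nonmissing += present
    with np.errstate(invalid="ignore"):
        Y = np.where(nonmissing > 0, acc / np.maximum(nonmissing, 1.0), np.nan)

    keep_cols = nonmissing > 0
    from .projection import bin_centers as _centers
    x = _centers(n_bins)[keep_cols] / 100.0
    null_r2 = r2_matrix(Y[:, keep_cols], x, grid)
    maxstat = null_r2.max(axis=1)
    return PermutationNull(
        n_perm=n_perm, grid=grid, null_r2=null_r2, maxstat=maxstat,
        crit95=float(np.percentile(maxstat, 95, method="higher")),
        level=level,
    )


def group_series(
    participants: Sequence[ParticipantEvents],
    n_bins: int = 40,
    statistic: Statistic = "mean",
    measure: str = "",
    pooled: bool = False,
) -> BinnedSeries:
    """Group-level binned series: equal-weight average of per-participant
    series (default), or a pooled-events series behind the ``pooled`` flag."""
    if pooled:
        phase = np.concatenate([p.phase_pct for p in participants])
        vals = (None if statistic == "density"
                else np.concatenate([p.values for p in participants]))
        return bin_series(phase, vals, n_bins, statistic, measure=measure)
    stack = []
    counts_total = np.zeros(n_bins)
    for p in participants:
        s = bin_series(p.phase_pct, p.values, n_bins, statistic)
        stack.append(s.values)
        counts_total += s.counts
    with np.errstate(invalid="ignore"):
        mean_vals = np.nanmean(np.vstack(stack), axis=0)
    from .projection import bin_centers as _centers
    return BinnedSeries(measure=measure or statistic, n_bins=n_bins,
                        bin_centers=_centers(n_bins), values=mean_vals,
                        counts=counts_total, statistic=statistic)


def significant_ranges(
    sweep_result: SweepResult, null: PermutationNull,
) -> list[tuple[float, float]]:
    """Maximal contiguous grid runs where observed R^2 strictly exceeds the
    max-statistic critical value, as [low, high] cps intervals."""
    mask = sweep_result.r2_by_freq > null.crit95
    ranges: list[tuple[float, float]] = []
    i = 0
    g = sweep_result.grid
    while i < mask.size:
        if mask[i]:
            j = i
            while j + 1 < mask.size and mask[j + 1]:
                j += 1
            ranges.append((float(g[i]), float(g[j])))
            i = j + 1
        else:
            i += 1
    return ranges


def classify_band(best_freq: float, significant: bool) -> Band:
    if not significant:
        return "none"
    if TWO_CPS_BAND[0] <= best_freq <= TWO_CPS_BAND[1]:
        return "two_cps"
    if FOUR_CPS_BAND[0] <= best_freq <= FOUR_CPS_BAND[1]:
        return "four_cps"
    if best_freq > HIGH_BAND_MIN:
        return "high"
    return "none"


def participant_test(
    participant_id: str,
    measure: str,
    sweep_result: SweepResult,
    null: PermutationNull,
    alpha: float = 0.05,
    rule: Literal["maxstat", "perfreq"] = "maxstat",
) -> ParticipantResult:
    """Participant-level NHST against their own shuffled null.

    Default rule compares the observed maximum R^2 over the grid to the
    (1-alpha) quantile of the permutation max-statistic; the per-frequency
    alternative tests each grid frequency against its own null quantile.
    """
    obs = sweep_result.r2_by_freq
    if rule == "maxstat":
        significant = bool(np.nanmax(obs) > null.critical(alpha))
    else:
        significant = bool(np.any(obs > null.per_freq_critical(alpha)))
    best_i = int(np.nanargmax(obs))
    best_freq = float(sweep_result.grid[best_i])
    return ParticipantResult(
        participant_id=participant_id, measure=measure,
        best_freq=best_freq, best_r2=float(obs[best_i]),
        significant=significant,
        band=classify_band(best_freq, significant),
    )


def cohort_summary(
    results: dict[str, Sequence[ParticipantResult]],
) -> dict:
    """Counts of significant participants per band and measure, plus
    cross-measure band agreement among multiply-significant participants."""
    out: dict = {"bands": {}, "n": {}, "cross_measure_agreement": None}
    for measure, res in results.items():
        out["n"][measure] = len(res)
        counts = {"two_cps": 0, "four_cps": 0, "high": 0, "none": 0}
        for r in res:
            counts[r.band] += 1
        out["bands"][measure] = counts

    by_pid: dict[str, list[str]] = {}
    for res in results.values():
        for r in res:
            if r.significant:
                by_pid.setdefault(r.participant_id, []).append(r.band)
    multi = {pid: bands for pid, bands in by_pid.items() if len(bands) >= 2}
    if multi:
        agree = sum(len(set(b)) == 1 for b in multi.values())
        out["cross_measure_agreement"] = agree / len(multi)
    return out


def stride_duration_correlation(
    stride_durations: dict[str, float],
    sweeps: dict[str, SweepResult],
) -> list[dict]:
    """Rank correlations of per-participant stride duration with oscillation
    metrics: R^2 at 2 and 4 cps, best frequency in cps, and best frequency
    converted to Hz (cps / stride duration).  A frequency fixed in cps
    across participants is mechanically negatively correlated with duration
    once expressed in Hz; absence of correlation in cps is the signature of
    gait-phase (not clock-time) locking."""
    pids = sorted(set(stride_durations) & set(sweeps))
    if len(pids) < 5:
        raise ValueError("need at least 5 participants")
    dur = np.array([stride_durations[p] for p in pids])
    rows = []
    metrics = {
        "r2_at_2cps": np.array([sweeps[p].r2_at(2.0) for p in pids]),
        "r2_at_4cps": np.array([sweeps[p].r2_at(4.0) for p in pids]),
        "best_freq_cps": np.array([sweeps[p].best_freq for p in pids]),
        "best_freq_hz": np.array(
            [sweeps[p].best_freq / stride_durations[p] for p in pids]),
    }
    degenerate = np.ptp(dur) == 0
    for name, vals in metrics.items():
        if degenerate or np.ptp(vals) == 0:
            rows.append({"metric": name, "rho": np.nan, "p": np.nan,
                         "flag": "degenerate"})
            continue
        rho, p = stats.spearmanr(dur, vals)
        rows.append({"metric": name, "rho": float(rho), "p": float(p),
                     "flag": ""})
    return rows
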