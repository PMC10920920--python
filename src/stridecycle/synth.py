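"""Synthetic walking-psychophysics sessions with known ground truth.

Emulates the study design this package analyses: participants walk 9 s
trials at 1.1 m/s while detecting brief (20 ms) visual targets.  Vertical
head position oscillates with one raised-cosine arc per step (two troughs
per stride, i.e. per pair of footfalls), with per-step duration jitter,
additive sensor noise and optional slow drift.  Up to eight targets per
trial are scheduled at jittered anchor times under a minimum 0.8 s
inter-target interval, each independently withheld with 10% probability.
Detection outcomes carry a stride-phase oscillation with participant-specific
frequency (cycles per stride), amplitude and phase on hit probability and
reaction time:

    P(hit | x) = base + A_acc * cos(2*pi*f*x + phi),   x = stride fraction
    RT(x)      = base_rt - A_rt * cos(2*pi*f*x + phi) + noise

so every downstream stage (gait extraction, phase projection, Fourier sweep,
prevalence, phase clustering) can be tested against known parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gait import HeadTrace
from .projection import phase_from_troughs
from .quest import QuestConfig, quest_init, quest_quantiles, quest_update


@dataclass
class ParticipantSpec:
    """Ground-truth parameters of one simulated participant."""

    participant_id: str
    stride_duration_mean: float = 1.18   # s
    stride_duration_sd: float = 0.04     # s, per-step jitter (stride scale)
    tempo_trial_sd: float = 0.03         # fractional per-trial tempo spread
    head_amplitude: float = 0.025        # m, half peak-to-trough per step
    head_noise_sd: float = 0.003         # m
    osc_frequency: float = 2.0           # cycles per stride
    osc_amplitude_acc: float = 0.12      # probability units
    osc_amplitude_rt: float = 0.03       # s
    osc_phase: float = -np.pi            # rad; peak accuracy at 25% phase
    base_hit_rate: float = 0.75
    base_rt: float = 0.48                # s
    rt_noise_sd: float = 0.08            # s
    observer_threshold: float = 0.44     # grayscale
    observer_width: float = 0.02         # grayscale

    def validate(self) -> None:
        if self.stride_duration_mean <= 0:
            raise ValueError("stride_duration_mean must be positive")
        if not (0 < self.osc_frequency <= 10):
            raise ValueError("osc_frequency must be in (0, 10]")
        if (self.base_hit_rate - self.osc_amplitude_acc < 0
                or self.base_hit_rate + self.osc_amplitude_acc > 1):
            raise ValueError("hit-rate oscillation exceeds [0, 1]")
        if self.base_rt - self.osc_amplitude_rt <= 0:
            raise ValueError("RT oscillation makes mean RT non-positive")


#: Default anchor layout: eight anchors 0.95 s apart, the densest layout
#: that fits a 9 s trial with the +-0.5 s jitter and reproduces realized
#: inter-target intervals near 0.9 s under the 0.8 s minimum.
DEFAULT_ANCHORS = (1.0, 1.95, 2.9, 3.85, 4.8, 5.75, 6.7, 7.65)


@dataclass
class SessionConfig:
    """Session layout shared by all participants."""

    n_participants: int = 36
    n_walking_trials: int = 140
    n_stationary_trials: int = 40
    trial_duration: float = 9.0          # s
    frame_rate: float = 90.0             # Hz
    walking_speed: float = 1.1           # m/s
    target_anchors: tuple = DEFAULT_ANCHORS
    target_jitter: float = 0.5           # s, +- uniform
    withhold_probability: float = 0.1
    min_iti: float = 0.8                 # s
    target_duration: float = 0.02        # s
    rng_seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        a = np.asarray(self.target_anchors, dtype=float)
        if a.size > 8:
            problems.append("at most 8 target anchors per trial")
        if a.size >= 2 and np.any(np.diff(a) < self.min_iti):
            problems.append("consecutive anchors closer than min_iti")
        if a.size and a[0] - self.target_jitter <= 0:
            problems.append("first anchor's jitter window leaves the trial")
        latest = self.trial_duration - self.target_duration
        if a.size and a[-1] + self.target_jitter > latest:
            problems.append("last anchor's jitter window leaves the trial")
        if self.trial_duration * self.frame_rate < 2:
            problems.append("trial too short for head-trace simulation")
        if not (0 <= self.withhold_probability <= 1):
            problems.append("withhold_probability must be in [0, 1]")
        return problems


@dataclass
class CohortSpec:
    """Distribution from which participant specs are drawn.

    The default mixture follows the heterogeneity the analysis is designed
    to detect: some participants oscillate at ~2 cycles per stride (the step
    rate), some at ~4, some not at all; oscillation phases cluster across
    participants (von Mises) around a peak in the swing phase.
    """

    frequencies: tuple = (2.0, 4.0, None)    # None = no oscillation
    weights: tuple = (1 / 3, 1 / 3, 1 / 3)
    osc_amplitude_acc: float = 0.12
    osc_amplitude_rt: float = 0.03
    phase_center: float = -np.pi             # rad
    phase_kappa: float = 2.0                 # 0 = phases uniform
    stride_mean: float = 1.18                # s, population mean
    stride_between_sd: float = 0.069         # s, across participants
    stride_within_sd: float = 0.04           # s, per-step jitter
    false_alarm_rate: float = 0.0            # Poisson responses / trial


@dataclass
class SimulatedTrace:
    """A head trace plus its generator-side ground truth."""

    trace: HeadTrace
    true_troughs: np.ndarray     # footfall times in (0, trial end]

    def true_phase(self, times: np.ndarray,
                   extrapolate: bool = False) -> np.ndarray:
        """Ground-truth stride-phase percentile at arbitrary times."""
        phase, _ = phase_from_troughs(np.asarray(times, dtype=float),
                                      self.true_troughs,
                                      extrapolate=extrapolate)
        return phase


def _draw_step_durations(step_mean: float, step_sd: float, n: int,
                         rng: np.random.Generator,
                         floor: float = 0.05) -> np.ndarray:
    """Normal step durations truncated positive (resampled below floor)."""
    d = rng.normal(step_mean, step_sd, size=n)
    for _ in range(100):
        bad = d <= floor
        if not bad.any():
            return d
        d[bad] = rng.normal(step_mean, step_sd, size=int(bad.sum()))
    raise RuntimeError("step-duration truncation failed to converge")


def simulate_head_trace(
    spec: ParticipantSpec,
    config: SessionConfig,
    rng: np.random.Generator,
    initial_step_fraction: float | None = None,
    gait_onset_delay: float | None = None,
    max_onset_delay: float = 1.2,
    drift_slope: float = 0.0,
    baseline_height: float = 1.60,
) -> SimulatedTrace:
    """Simulate one trial's vertical head motion with known footfall times.

    The vertical trace is a concatenation of per-step raised-cosine arcs
    (trough at each footfall, peak mid-swing), so step-duration jitter
    accumulates realistically instead of being absorbed by a global
    sinusoid.  By default each trial begins with a gait-initiation latency
    drawn from U(0, ``max_onset_delay``) - the participant stands for a
    moment before the first step - which decouples footfall timing from
    trial onset (and hence from the fixed target-anchor grid); without it
    the first trough always falls within one step of t=0 and target phases
    pick up a spurious stride-frequency ripple.  Passing
    ``gait_onset_delay`` fixes that latency; passing ``initial_step_fraction``
    in (0, 1] instead starts the trial mid-step, that fraction of a step
    before the next footfall (1.0 = a full step), for deterministic
    constructions.  Forward position advances at the walking speed.
    """
    spec.validate()
    problems = config.validate()
    if problems:
        raise ValueError("; ".join(problems))
    # Trial-to-trial pace variation: the whole trial walks a little faster
    # or slower than the participant's mean tempo.
    tempo = 1.0
    if spec.tempo_trial_sd > 0:
        tempo = max(0.5, 1.0 + rng.normal(0.0, spec.tempo_trial_sd))
    step_mean = tempo * spec.stride_duration_mean / 2.0
    step_sd = spec.stride_duration_sd / np.sqrt(2.0)
    duration = config.trial_duration
    n_frames = int(round(duration * config.frame_rate))
    t = np.arange(n_frames) / config.frame_rate

    n_steps = int(np.ceil(duration / max(step_mean, 0.1))) + 4
    if step_sd > 0:
        durs = _draw_step_durations(step_mean, step_sd, n_steps, rng)
    else:
        durs = np.full(n_steps, step_mean)
    if initial_step_fraction is not None:
        frac = float(initial_step_fraction)
        if not (0 < frac <= 1):
            raise ValueError("initial_step_fraction must be in (0, 1]")
        start0 = -(1.0 - frac) * durs[0]
    elif gait_onset_delay is not None:
        start0 = float(gait_onset_delay)
    else:
        start0 = rng.uniform(0.0, max_onset_delay)

    # Step boundaries; start0 > 0 means the walk begins after a standing
    # interval, start0 <= 0 that the current step began before t=0.
    boundaries = start0 + np.concatenate([[0.0], np.cumsum(durs)])
    while boundaries[-1] < duration + step_mean:
        extra = (_draw_step_durations(step_mean, step_sd, 4, rng)
                 if step_sd > 0 else np.full(4, step_mean))
        boundaries = np.concatenate([boundaries,
                                     boundaries[-1] + np.cumsum(extra)])

    k = np.clip(np.searchsorted(boundaries, t, side="right") - 1,
                0, boundaries.size - 2)
    u = (t - boundaries[k]) / (boundaries[k + 1] - boundaries[k])
    height = spec.head_amplitude * (1.0 - np.cos(2 * np.pi * u))
    if start0 > 0:
        # Standing before gait onset: head at mid-range, easing down into
        # the first footfall over the last 0.3 s before the walk starts.
        standing = t < start0
        ease = np.clip((start0 - t[standing]) / 0.3, 0.0, 1.0)
        height[standing] = spec.head_amplitude * np.sin(np.pi / 2 * ease) ** 2
    height = height + baseline_height + drift_slope * t
    if spec.head_noise_sd > 0:
        height = height + rng.normal(0.0, spec.head_noise_sd, size=n_frames)

    troughs = boundaries[(boundaries > 1e-12) & (boundaries <= t[-1])]
    trace = HeadTrace(spec.participant_id, -1, t, height)
    return SimulatedTrace(trace=trace, true_troughs=troughs)


def schedule_targets(config: SessionConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Jittered, withholding-thinned target onsets for one trial.

    Each anchor is first withheld with the configured probability, then the
    surviving onset is drawn uniformly from the anchor's jitter window
    truncated to respect the minimum inter-target interval relative to the
    previously presented target (the window is never empty under the default
    layout).  Onsets are returned sorted and all pairwise gaps respect the
    minimum interval.
    """
    problems = config.validate()
    if problems:
        raise ValueError("; ".join(problems))
    latest = config.trial_duration - config.target_duration
    onsets = []
    prev = -np.inf
    for a in config.target_anchors:
        if rng.random() < config.withhold_probability:
            continue
        lo = max(a - config.target_jitter, prev + config.min_iti, 1e-9)
        hi = min(a + config.target_jitter, latest)
        if lo > hi:
            continue  # infeasible window after truncation: target dropped
        onset = rng.uniform(lo, hi)
        onsets.append(onset)
        prev = onset
    return np.asarray(onsets)


def hit_probability(phase_pct: np.ndarray, spec: ParticipantSpec) -> np.ndarray:
    """Generating hit-rate curve at stride-phase percentiles."""
    x = np.asarray(phase_pct, dtype=float) / 100.0
    return (spec.base_hit_rate + spec.osc_amplitude_acc
            * np.cos(2 * np.pi * spec.osc_frequency * x + spec.osc_phase))


def mean_rt(phase_pct: np.ndarray, spec: ParticipantSpec) -> np.ndarray:
    """Generating mean-RT curve (anti-modulated with accuracy by default:
    faster responses at the accuracy-optimal phase)."""
    x = np.asarray(phase_pct, dtype=float) / 100.0
    return (spec.base_rt - spec.osc_amplitude_rt
            * np.cos(2 * np.pi * spec.osc_frequency * x + spec.osc_phase))


MIN_RT_S = 0.15


def simulate_outcomes(
    onsets: np.ndarray,
    spec: ParticipantSpec,
    phase_pct,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw detection outcomes and reaction times for scheduled targets.

    ``phase_pct`` is an array of stride-phase percentiles or a callable
    returning them for the onset times.  Hits are Bernoulli draws from the
    generating cosine; hits get RT = mean_rt + Gaussian noise truncated at
    0.15 s and misses produce no response.  Returns (hit in {0,1}, rt with
    NaN for misses).
    """
    onsets = np.asarray(onsets, dtype=float)
    phase = np.asarray(phase_pct(onsets) if callable(phase_pct)
                       else phase_pct, dtype=float)
    if phase.shape != onsets.shape or np.isnan(phase).any():
        raise ValueError("a stride phase is required for every onset")
    p = hit_probability(phase, spec)
    hit = (rng.random(onsets.size) < p).astype(int)
    rt = np.full(onsets.size, np.nan)
    n_hit = int(hit.sum())
    if n_hit:
        noise = rng.normal(0.0, spec.rt_noise_sd, size=n_hit)
        rt[hit == 1] = np.maximum(mean_rt(phase[hit == 1], spec) + noise,
                                  MIN_RT_S)
    return hit, rt


OBSERVER_GUESS = 0.5
OBSERVER_LAPSE = 0.01


def observer_hit_probability(intensity, spec: ParticipantSpec):
    """Closed-form psychometric of the simulated staircase observer:
    P(hit) = guess + (1 - guess - lapse) * Phi((c - threshold)/width)."""
    from scipy.stats import norm
    c = np.asarray(intensity, dtype=float)
    if np.any(c < 0.4) or np.any(c > 1.0):
        raise ValueError("intensity must be within [0.4, 1]")
    z = (c - spec.observer_threshold) / spec.observer_width
    return OBSERVER_GUESS + (1 - OBSERVER_GUESS - OBSERVER_LAPSE) * norm.cdf(z)


def simulate_staircase_observer(intensity: float, spec: ParticipantSpec,
                                rng: np.random.Generator) -> bool:
    """One Bernoulli detection outcome of the simulated observer."""
    return bool(rng.random() < observer_hit_probability(intensity, spec))


def draw_participant_spec(cohort: CohortSpec, participant_id: str,
                          rng: np.random.Generator) -> ParticipantSpec:
    """Draw one participant's ground-truth parameters from the cohort
    distribution (oscillation band, stride tempo, phase, observer)."""
    i = rng.choice(len(cohort.frequencies),
                   p=np.asarray(cohort.weights) / np.sum(cohort.weights))
    freq = cohort.frequencies[i]
    modulated = freq is not None
    phase = float(np.mod(rng.vonmises(cohort.phase_center,
                                      cohort.phase_kappa) + np.pi,
                         2 * np.pi) - np.pi) if modulated else 0.0
    stride = float(np.clip(rng.normal(cohort.stride_mean,
                                      cohort.stride_between_sd), 0.9, 1.5))
    spec = ParticipantSpec(
        participant_id=participant_id,
        stride_duration_mean=stride,
        stride_duration_sd=cohort.stride_within_sd,
        head_amplitude=float(np.clip(rng.normal(0.025, 0.004), 0.01, 0.05)),
        osc_frequency=float(freq) if modulated else 2.0,
        osc_amplitude_acc=cohort.osc_amplitude_acc if modulated else 0.0,
        osc_amplitude_rt=cohort.osc_amplitude_rt if modulated else 0.0,
        osc_phase=phase,
        base_rt=float(np.clip(rng.normal(0.48, 0.03), 0.3, 0.7)),
        observer_threshold=float(np.clip(rng.normal(0.44, 0.01), 0.41, 0.5)),
    )
    spec.validate()
    return spec


@dataclass
class CohortPaths:
    out_dir: Path
    frames: Path
    targets: Path
    responses: Path
    manifest: Path
    ground_truth: Path
    true_troughs: Path


def _participant_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Documented sub-stream derivation: one spawned child per participant
    from the master seed, so adding participants never perturbs earlier
    streams."""
    return [np.random.default_rng(c)
            for c in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(
    config: SessionConfig,
    cohort: CohortSpec | None = None,
    out_dir: str | Path = "cohort",
    seed: int | None = None,
    with_staircase: bool = True,
) -> CohortPaths:
    """Generate a complete on-disk synthetic dataset.

    Writes ``frames.csv`` (head position per 90 Hz frame), ``targets.csv``
    (onsets, intensities, outcomes, RTs), ``responses.csv`` (press onsets),
    ``manifest.json`` (config echo + seed), ``ground_truth.json`` (every
    participant's true parameters) and ``true_troughs.csv`` (generator
    footfall times, for oracle tests).  Regeneration with the same seed is
    byte-identical.  When ``with_staircase`` is set, a QUEST staircase per
    participant assigns each target a contrast level from the seven
    posterior quantiles and is updated with the target's outcome.
    """
    cohort = cohort or CohortSpec()
    seed = config.rng_seed if seed is None else seed
    problems = config.validate()
    if problems:
        raise ValueError("; ".join(problems))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    frame_rows, target_rows, response_rows, trough_rows = [], [], [], []
    specs: list[ParticipantSpec] = []
    rngs = _participant_rngs(seed, config.n_participants)
    t_grid = (np.arange(int(round(config.trial_duration * config.frame_rate)))
              / config.frame_rate)
    mid = len(QuestConfig().quantile_percentiles) // 2

    for p_idx in range(config.n_participants):
        rng = rngs[p_idx]
        pid = f"P{p_idx:02d}"
        spec = draw_participant_spec(cohort, pid, rng)
        specs.append(spec)
        qstate = quest_init() if with_staircase else None

        trials = ([("walk", i) for i in range(config.n_walking_trials)]
                  + [("stand", i) for i in range(config.n_stationary_trials)])
        for cond, i in trials:
            trial_id = (i if cond == "walk"
                        else config.n_walking_trials + i)
            onsets = schedule_targets(config, rng)
            if cond == "walk":
                sim = simulate_head_trace(spec, config, rng)
                sim.trace.trial_id = trial_id
                height = sim.trace.height
                x_fwd = config.walking_speed * t_grid
                phases = sim.true_phase(onsets, extrapolate=True)
                hit, rt = simulate_outcomes(onsets, spec, phases, rng)
                trough_rows.extend(
                    {"participant_id": pid, "trial_id": trial_id,
                     "trough_s": float(tt)} for tt in sim.true_troughs)
            else:
                height = 1.60 + rng.normal(0.0, spec.head_noise_sd,
                                           size=t_grid.size)
                x_fwd = np.zeros_like(t_grid)
                p = np.full(onsets.size, spec.base_hit_rate)
                hit = (rng.random(onsets.size) < p).astype(int)
                rt = np.full(onsets.size, np.nan)
                if hit.sum():
                    rt[hit == 1] = np.maximum(
                        spec.base_rt + rng.normal(0.0, spec.rt_noise_sd,
                                                  size=int(hit.sum())),
                        MIN_RT_S)

            levels = np.zeros(onsets.size, dtype=int)
            intensities = np.full(onsets.size, QuestConfig().initial_intensity)
            if qstate is not None:
                for j in range(onsets.size):
                    qlevels = quest_quantiles(qstate)
                    lvl = int(rng.integers(len(qlevels)))
                    intensities[j] = float(qlevels[lvl])
                    levels[j] = lvl - mid
                    qstate = quest_update(qstate, intensities[j],
                                          bool(hit[j]))

            frame_rows.append(pd.DataFrame({
                "participant_id": pid, "trial_id": trial_id,
                "condition": cond, "t": t_grid,
                "head_x": x_fwd, "head_y": 0.0, "head_z": height,
            }))
            for j in range(onsets.size):
                target_rows.append({
                    "participant_id": pid, "trial_id": trial_id,
                    "onset_s": float(onsets[j]),
                    "intensity": float(intensities[j]),
                    "quantile_level": int(levels[j]),
                    "outcome": "hit" if hit[j] else "miss",
                    "rt_s": float(rt[j]) if hit[j] else np.nan,
                })
                if hit[j]:
                    response_rows.append({
                        "participant_id": pid, "trial_id": trial_id,
                        "press_onset_s": float(onsets[j] + rt[j]),
                    })
            if cohort.false_alarm_rate > 0:
                for _ in range(rng.poisson(cohort.false_alarm_rate)):
                    response_rows.append({
                        "participant_id": pid, "trial_id": trial_id,
                        "press_onset_s": float(
                            rng.uniform(0, config.trial_duration)),
                    })

    paths = CohortPaths(
        out_dir=out, frames=out / "frames.csv", targets=out / "targets.csv",
        responses=out / "responses.csv", manifest=out / "manifest.json",
        ground_truth=out / "ground_truth.json",
        true_troughs=out / "true_troughs.csv",
    )
    pd.concat(frame_rows, ignore_index=True).to_csv(
        paths.frames, index=False, float_format="%.6f")
    pd.DataFrame(target_rows, columns=[
        "participant_id", "trial_id", "onset_s", "intensity",
        "quantile_level", "outcome", "rt_s",
    ]).to_csv(paths.targets, index=False, float_format="%.6f")
    pd.DataFrame(response_rows, columns=[
        "participant_id", "trial_id", "press_onset_s",
    ]).to_csv(paths.responses, index=False, float_format="%.6f")
    pd.DataFrame(trough_rows, columns=[
        "participant_id", "trial_id", "trough_s",
    ]).to_csv(paths.true_troughs, index=False, float_format="%.6f")

    with open(paths.manifest, "w") as fh:
        json.dump({"config": asdict(config), "seed": seed,
                   "cohort": asdict(cohort)},
                  fh, indent=2, sort_keys=True)
    with open(paths.ground_truth, "w") as fh:
        json.dump({"participants": [asdict(s) for s in specs]},
                  fh, indent=2, sort_keys=True)
    return paths


def read_ground_truth(path: str | Path) -> list[ParticipantSpec]:
    with open(path) as fh:
        data = json.load(fh)
    return [ParticipantSpec(**d) for d in data["participants"]]


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
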