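"""QUEST adaptive staircase and psychometric fitting.

The staircase maintains a Bayesian posterior over the detection threshold on
a discrete grid of grayscale target contrasts.  Internally intensities are
expressed in decibels of the raw grayscale value, dB(c) = 20*log10(c), the
scale on which the staircase's printed summary statistics are reported.  The
likelihood is the classic QUEST Weibull in dB units with guess floor and
lapse, shifted so that the tracked threshold parameter is the intensity at
which the observer is correct at the staircase's target rate (75%); placing
trials at posterior quantiles of that parameter is what holds observed
accuracy near the target rate.  Trial contrasts are drawn from seven
posterior quantiles (levels Q-3..Q+3) so a psychometric function can be
refitted offline; the offline refit uses a cumulative normal with fixed
guess and a small free lapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize, stats


@dataclass
class QuestConfig:
    initial_intensity: float = 0.45     # grayscale (background is 0.4)
    prior_sd: float = 2.0               # dB
    beta: float = 3.5                   # Weibull slope
    lapse: float = 0.01
    guess: float = 0.5
    grain: float = 0.004                # grayscale step of the grid
    range_low: float = 0.4
    range_high: float = 1.0
    p_target: float = 0.75              # accuracy the staircase maintains
    quantile_percentiles: tuple = (25.0, 32.25, 37.5, 50.0, 62.5, 68.75, 75.0)

    def validate(self) -> list[str]:
        problems = []
        if not (self.range_low < self.initial_intensity < self.range_high):
            problems.append("initial_intensity outside intensity range")
        n = (self.range_high - self.range_low) / self.grain
        if abs(n - round(n)) > 1e-9:
            problems.append("grain does not divide the intensity range")
        q = np.asarray(self.quantile_percentiles)
        if np.any(np.diff(q) <= 0) or q[0] < 0 or q[-1] > 100:
            problems.append("quantile percentiles must be strictly "
                            "increasing within [0, 100]")
        if not (self.guess < self.p_target < 1 - self.lapse):
            problems.append("p_target must lie between guess and 1-lapse")
        return problems


@dataclass
class QuestState:
    config: QuestConfig
    intensities: np.ndarray             # grid, grayscale
    intensities_db: np.ndarray
    posterior: np.ndarray               # pmf over threshold grid
    threshold_offset_db: float          # shift placing p_target at offset 0

    def posterior_mean(self) -> float:
        """Posterior-mean threshold intensity (grayscale)."""
        return float(np.sum(self.posterior * self.intensities))


@dataclass
class StaircaseLog:
    intensity: np.ndarray
    level_index: np.ndarray             # -3..+3; familiarization rows get 0
    outcome: np.ndarray                 # 1 hit, 0 miss
    familiarization: np.ndarray         # bool mask; excluded from fits


@dataclass
class PsychometricFit:
    threshold50: float                  # intensity at the half-way point
    width_5_95: float                   # 5th-to-95th percentile span
    slope: float                        # max derivative, probability/intensity
    mu: float
    sigma: float
    lapse: float
    flags: list[str] = field(default_factory=list)


def db(intensity: np.ndarray | float) -> np.ndarray | float:
    """Decibel transform of raw grayscale intensity, 20*log10(c)."""
    return 20.0 * np.log10(intensity)


def _weibull_offset(cfg: QuestConfig) -> float:
    """dB offset at which the Weibull psychometric crosses p_target.

    Solving guess + (1-guess-lapse)*(1 - exp(-10^(beta*d/20))) = p_target
    gives d = (20/beta)*log10(-log(1 - (p_target-guess)/(1-guess-lapse))).
    """
    frac = (cfg.p_target - cfg.guess) / (1 - cfg.guess - cfg.lapse)
    return float(20.0 / cfg.beta * np.log10(-np.log1p(-frac)))


def _weibull_p(delta_db: np.ndarray, cfg: QuestConfig) -> np.ndarray:
    """Hit probability at dB offset ``delta_db`` from the Weibull anchor."""
    u = 10.0 ** (cfg.beta * delta_db / 20.0)
    return cfg.guess + (1 - cfg.guess - cfg.lapse) * (1.0 - np.exp(-u))


def quest_init(config: QuestConfig | None = None) -> QuestState:
    """Initialize the staircase: intensity grid and Gaussian threshold prior.

    The prior over the threshold is Gaussian in dB units, centred on the
    initial intensity with the configured standard deviation, discretized on
    the grid and normalized.
    """
    cfg = config or QuestConfig()
    problems = cfg.validate()
    if problems:
        raise ValueError("; ".join(problems))
    n = int(round((cfg.range_high - cfg.range_low) / cfg.grain)) + 1
    grid = np.linspace(cfg.range_low, cfg.range_high, n)
    grid_db = db(grid)
    prior = np.exp(-0.5 * ((grid_db - db(cfg.initial_intensity))
                           / cfg.prior_sd) ** 2)
    prior /= prior.sum()
    return QuestState(
        config=cfg, intensities=grid, intensities_db=grid_db,
        posterior=prior, threshold_offset_db=_weibull_offset(cfg),
    )


def likelihood_hit(state: QuestState, tested_intensity: float) -> np.ndarray:
    """P(hit | threshold = each grid value) at the tested intensity."""
    delta = (db(tested_intensity) - state.intensities_db
             + state.threshold_offset_db)
    return _weibull_p(delta, state.config)


def quest_update(state: QuestState, tested_intensity: float,
                 hit: bool) -> QuestState:
    """Bayesian update of the threshold posterior after one target."""
    lik = likelihood_hit(state, tested_intensity)
    post = state.posterior * (lik if hit else (1.0 - lik))
    total = post.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("posterior mass vanished during update")
    return QuestState(
        config=state.config, intensities=state.intensities,
        intensities_db=state.intensities_db, posterior=post / total,
        threshold_offset_db=state.threshold_offset_db,
    )


def quest_quantiles(state: QuestState,
                    percentiles: tuple | None = None) -> np.ndarray:
    """Posterior quantile intensities for the seven contrast levels.

    Inverse-CDF of the discrete posterior snapped to the grid; monotone
    non-decreasing across levels by construction.
    """
    q = np.asarray(percentiles if percentiles is not None
                   else state.config.quantile_percentiles, dtype=float)
    cdf = np.cumsum(state.posterior)
    idx = np.searchsorted(cdf, q / 100.0, side="left")
    idx = np.clip(idx, 0, state.intensities.size - 1)
    return state.intensities[idx]


def run_staircase(
    observer: Callable[[float, np.random.Generator], bool],
    config: QuestConfig | None = None,
    n_targets: int = 900,
    rng: np.random.Generator | int | None = None,
    n_familiarization: int = 0,
) -> tuple[StaircaseLog, QuestState]:
    """Drive the staircase against an observer for ``n_targets`` targets.

    Optional familiarization targets are presented first at the fixed
    initial intensity without updating the posterior and are flagged in the
    log (excluded from fits).  Each staircase target draws its contrast
    uniformly from the seven posterior quantile levels.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    state = quest_init(config)
    cfg = state.config
    total = n_familiarization + n_targets
    intensity = np.empty(total)
    level = np.zeros(total, dtype=int)
    outcome = np.zeros(total, dtype=int)
    famil = np.zeros(total, dtype=bool)

    for i in range(n_familiarization):
        intensity[i] = cfg.initial_intensity
        famil[i] = True
        outcome[i] = int(observer(cfg.initial_intensity, rng))

    n_levels = len(cfg.quantile_percentiles)
    mid = n_levels // 2
    for i in range(n_familiarization, total):
        levels = quest_quantiles(state)
        j = int(rng.integers(n_levels))
        c = float(levels[j])
        hit = bool(observer(c, rng))
        state = quest_update(state, c, hit)
        intensity[i] = c
        level[i] = j - mid
        outcome[i] = int(hit)
    return StaircaseLog(intensity=intensity, level_index=level,
                        outcome=outcome, familiarization=famil), state


def make_normal_observer(
    threshold: float, width: float,
    guess: float = 0.5, lapse: float = 0.01,
) -> Callable[[float, np.random.Generator], bool]:
    """Simulated observer with a cumulative-normal psychometric function,
    P(hit) = guess + (1-guess-lapse) * Phi((c - threshold)/width)."""

    def observer(intensity: float, rng: np.random.Generator) -> bool:
        p = guess + (1 - guess - lapse) * stats.norm.cdf(
            (intensity - threshold) / width)
        return bool(rng.random() < p)

    return observer


def fit_psychometric(
    level_intensities: np.ndarray,
    hits_per_level: np.ndarray,
    trials_per_level: np.ndarray,
    guess: float = 0.5,
    max_lapse: float = 0.05,
) -> PsychometricFit:
    """Maximum-likelihood cumulative-normal fit to per-level detection data.

    Model: P(hit) = guess + (1 - guess - lapse) * Phi((c - mu)/sigma) with
    fixed guess and lapse free on [0, max_lapse].  The 50% threshold is the
    intensity at the midpoint between guess and 1 - lapse (equal to mu);
    width is the 5-to-95% span sigma * (z_.95 - z_.05); slope is the maximum
    derivative of the fitted curve.
    """
    c = np.asarray(level_intensities, dtype=float)
    k = np.asarray(hits_per_level, dtype=float)
    m = np.asarray(trials_per_level, dtype=float)
    used = m > 0
    c, k, m = c[used], k[used], m[used]
    if np.unique(c).size < 4:
        raise ValueError("need trials at >= 4 distinct intensities")

    def nll(params: np.ndarray) -> float:
        mu, log_sigma, lapse = params
        sigma = np.exp(log_sigma)
        p = guess + (1 - guess - lapse) * stats.norm.cdf((c - mu) / sigma)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return float(-np.sum(k * np.log(p) + (m - k) * np.log1p(-p)))

    span = max(c.max() - c.min(), 1e-3)
    x0 = np.array([float(np.average(c, weights=m)), np.log(span / 4), 0.01])
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B",
        bounds=[(c.min() - 10 * span, c.max() + 10 * span),
                (np.log(span * 1e-3), np.log(span * 100)),
                (0.0, max_lapse)],
    )
    flags = []
    if not res.success:
        flags.append(f"non-convergence: {res.message}")
    mu, sigma, lapse = float(res.x[0]), float(np.exp(res.x[1])), float(res.x[2])
    if mu < c.min():
        flags.append("threshold-below-tested-range")
    if mu > c.max():
        flags.append("threshold-above-tested-range")
    z_span = stats.norm.ppf(0.95) - stats.norm.ppf(0.05)
    return PsychometricFit(
        threshold50=mu, width_5_95=sigma * z_span,
        slope=(1 - guess - lapse) / (sigma * np.sqrt(2 * np.pi)),
        mu=mu, sigma=sigma, lapse=lapse, flags=flags,
    )
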