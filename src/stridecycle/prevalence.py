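"""Bayesian inference of population prevalence of within-participant effects.

Given k of n participants significant at a per-test false-positive rate
alpha, the probability that a randomly drawn participant tests significant is

    theta(gamma) = (1 - gamma) * alpha + gamma * sensitivity

where gamma is the population prevalence of the true effect and sensitivity
is the assumed within-participant power (1.0 by default).  Under a uniform
prior on gamma the posterior is proportional to the binomial likelihood
Binom(k; n, theta(gamma)); the point estimate reported is the maximum a
posteriori (MAP) value together with the 95% highest posterior density
interval (HPDI), the shortest interval holding 95% of the posterior mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_GRID_POINTS = 2001


def _validate(k: int, n: int, alpha: float) -> None:
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")


@dataclass
class PrevalencePosterior:
    k: int
    n: int
    alpha: float
    sensitivity: float
    gamma_grid: np.ndarray
    density: np.ndarray
    map: float
    hpdi_low: float
    hpdi_high: float

    def to_dict(self) -> dict:
        return {"k": self.k, "n": self.n, "alpha": self.alpha,
                "map": round(self.map, 4),
                "hpdi": [round(self.hpdi_low, 4), round(self.hpdi_high, 4)]}


def prevalence_map(k: int, n: int, alpha: float = 0.05,
                   sensitivity: float = 1.0) -> float:
    """Closed-form MAP of the prevalence posterior.

    The binomial likelihood in theta is maximized at theta = k/n, so the
    MAP prevalence is (k/n - alpha) / (sensitivity - alpha), clamped to
    [0, 1].
    """
    _validate(k, n, alpha)
    if sensitivity <= alpha:
        raise ValueError("sensitivity must exceed alpha")
    return float(np.clip((k / n - alpha) / (sensitivity - alpha), 0.0, 1.0))


def prevalence_posterior(
    k: int, n: int, alpha: float = 0.05,
    sensitivity: float = 1.0,
    grid: int | np.ndarray = DEFAULT_GRID_POINTS,
    hpdi_mass: float = 0.95,
) -> PrevalencePosterior:
    """Posterior density of prevalence on a uniform grid over [0, 1].

    Computed in log space for numerical stability and normalized by
    trapezoidal integration.  The grid argmax agrees with the closed-form
    MAP within one grid step.
    """
    _validate(k, n, alpha)
    if isinstance(grid, (int, np.integer)):
        if grid < 101:
            import warnings
            warnings.warn("prevalence grid below 101 points is coarse",
                          stacklevel=2)
        gamma = np.linspace(0.0, 1.0, int(grid))
    else:
        gamma = np.asarray(grid, dtype=float)
    theta = (1 - gamma) * alpha + gamma * sensitivity
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = k * np.log(theta) + (n - k) * np.log1p(-theta)
    loglik = np.where(np.isfinite(loglik), loglik, -np.inf)
    dens = np.exp(loglik - loglik.max())
    dens /= np.trapezoid(dens, gamma)
    lo, hi = hpdi((gamma, dens), mass=hpdi_mass)
    return PrevalencePosterior(
        k=k, n=n, alpha=alpha, sensitivity=sensitivity,
        gamma_grid=gamma, density=dens,
        map=float(gamma[np.argmax(dens)]), hpdi_low=lo, hpdi_high=hi,
    )


def hpdi(posterior: PrevalencePosterior | tuple, mass: float = 0.95,
         ) -> tuple[float, float]:
    """Highest posterior density interval by discrete water-filling.

    The density threshold is lowered until the included grid mass reaches
    ``mass``; the shortest contiguous interval covering the included points
    is returned.  If the included set is disconnected (multimodal density)
    the bridging span is included and a warning is logged.
    """
    if isinstance(posterior, PrevalencePosterior):
        gamma, dens = posterior.gamma_grid, posterior.density
    else:
        gamma, dens = posterior
    gamma = np.asarray(gamma, dtype=float)
    dens = np.asarray(dens, dtype=float)
    dx = gamma[1] - gamma[0]
    weights = dens * dx
    weights /= weights.sum()

    order = np.argsort(dens)[::-1]
    cum = np.cumsum(weights[order])
    n_in = int(np.searchsorted(cum, mass) + 1)
    included = np.sort(order[:n_in])
    if np.any(np.diff(included) > 1):
        import warnings
        warnings.warn("multimodal density: HPDI bridges modes", stacklevel=2)
    return float(gamma[included[0]]), float(gamma[included[-1]])
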