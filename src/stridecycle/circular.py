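"""Circular statistics for oscillation phases across participants.

The phase of each participant's best-fitting cosine model (radians) is a
point on the circle; consistency of preferred stride-cycle phase across
participants is tested with Rayleigh's test of angular uniformity.  The
reported quantities are the mean resultant length rbar (magnitude of the
average unit vector), the Rayleigh statistic Z = n * rbar^2, its p-value
from the standard second-order approximation, and the circular variance
1 - rbar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RayleighResult:
    n: int
    mean_angle: float       # radians, in (-pi, pi]
    rbar: float             # mean resultant length
    z: float                # n * rbar^2
    p: float
    circ_variance: float    # 1 - rbar


def wrap_angle(angles: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    a = np.mod(np.asarray(angles, dtype=float) + np.pi, 2 * np.pi) - np.pi
    return np.where(a == -np.pi, np.pi, a)


def mean_resultant(angles: np.ndarray) -> tuple[float, float]:
    """Mean resultant length and mean angle of a sample of angles."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle sample")
    c = np.cos(a).mean()
    s = np.sin(a).mean()
    return float(np.hypot(c, s)), float(np.arctan2(s, c))


def rayleigh_p(z: float, n: int) -> float:
    """Second-order approximation to the Rayleigh p-value (Zar), clamped to
    (0, 1]."""
    corr = (1.0
            + (2 * z - z**2) / (4 * n)
            - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2))
    p = np.exp(-z) * corr
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


def rayleigh_test(angles: np.ndarray) -> RayleighResult:
    """Rayleigh test of non-uniformity of angles on the circle.

    Small samples make the p approximation rough; a warning is issued below
    n = 10 and n < 4 is rejected outright.
    """
    a = np.asarray(angles, dtype=float)
    n = a.size
    if n < 4:
        raise ValueError("Rayleigh test needs n >= 4")
    if n < 10:
        import warnings
        warnings.warn("Rayleigh p-value approximation is rough below n=10",
                      stacklevel=2)
    rbar, mean_angle = mean_resultant(a)
    z = n * rbar**2
    return RayleighResult(
        n=n, mean_angle=mean_angle, rbar=rbar, z=float(z),
        p=rayleigh_p(float(z), n), circ_variance=1.0 - rbar,
    )


def rayleigh_test_permutation(
    angles: np.ndarray, n_perm: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> RayleighResult:
    """Rayleigh test with an exact-style p from uniform resampling of angles
    (flag-selectable alternative to the analytic approximation)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    res = rayleigh_test(angles)
    sims = rng.uniform(-np.pi, np.pi, size=(n_perm, res.n))
    c = np.cos(sims).mean(axis=1)
    s = np.sin(sims).mean(axis=1)
    z_null = res.n * (c**2 + s**2)
    p = (1 + np.sum(z_null >= res.z)) / (n_perm + 1)
    return RayleighResult(n=res.n, mean_angle=res.mean_angle, rbar=res.rbar,
                          z=res.z, p=float(p),
                          circ_variance=res.circ_variance)


def relative_change(series: np.ndarray) -> np.ndarray:
    """Normalize a series to relative change from its mean, (x - mean)/mean.

    Puts measures with different units (hit rate, seconds, density) on a
    common dimensionless scale for phase comparison; a cosine fit's
    amplitude afterwards equals the raw amplitude divided by the raw mean.
    """
    x = np.asarray(series, dtype=float)
    m = np.nanmean(x)
    if m == 0 or np.isnan(m):
        raise ValueError("series mean is zero; relative change undefined")
    return (x - m) / m
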