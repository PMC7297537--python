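"""Circular statistics for angular and axial bearing samples.

Bearings are degrees clockwise from (magnetic) north.  *Axial* samples
are directions meaningful modulo 180 degrees (an alignment rather than a
heading): they are analysed by doubling the angles, and the mean is
reported as an axis mu / mu+180.

Provided: the mean vector (mu, r), the Rayleigh test of uniformity with
the series-corrected large-sample p-value, the two-sample Watson U-squared
test (asymptotic table bound plus an optional permutation p-value), a
bootstrap confidence arc for the mean direction, and the two-level
scheme in which bearings are first averaged within each dog and the
grand mean is taken over the per-dog means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "CircularSample", "MeanVector", "RayleighResult", "WatsonResult",
    "mean_vector", "rayleigh_p", "rayleigh_test", "watson_u2_stat",
    "watson_u2", "circular_ci", "dog_level_means", "rose_bins",
]


@dataclass
class CircularSample:
    """A sample of bearings (degrees), angular or axial."""

    bearings: np.ndarray
    axial: bool = False
    level: str = "excursion"        # "excursion" | "dog"

    def __post_init__(self):
        self.bearings = np.asarray(self.bearings, dtype=float) % 360.0
        if self.bearings.size == 0:
            raise ValueError("empty circular sample")

    @property
    def n(self) -> int:
        return len(self.bearings)


@dataclass
class MeanVector:
    """Mean direction (or axis, in [0, 180)) and mean vector length."""

    mu: float
    r: float
    axial: bool = False

    @property
    def axis(self) -> str:
        """Axis notation "mu/mu+180" for axial data."""
        if not self.axial:
            return f"{self.mu:.0f}"
        return f"{self.mu:.0f}/{(self.mu + 180.0) % 360.0:.0f}"


@dataclass
class RayleighResult:
    n: int
    mu: float
    r: float
    z: float
    p: float
    axial: bool = False


@dataclass
class WatsonResult:
    u2: float
    p_bound: str                    # e.g. "<0.05" or ">0.5"
    p_asymptotic: float
    p_permutation: float | None = None


def _working_angles(sample: CircularSample) -> np.ndarray:
    """Radians used for vector algebra (doubled when axial)."""
    a = np.radians(sample.bearings)
    return 2.0 * a if sample.axial else a


def mean_vector(sample: CircularSample) -> MeanVector:
    """Mean resultant vector; axial samples are doubled, then halved back."""
    a = _working_angles(sample)
    c, s = float(np.mean(np.cos(a))), float(np.mean(np.sin(a)))
    r = min(math.hypot(c, s), 1.0)
    mu = math.degrees(math.atan2(s, c)) % 360.0
    if sample.axial:
        mu = (mu / 2.0) % 180.0
    return MeanVector(mu, r, axial=sample.axial)


def rayleigh_p(n: int, r: float) -> float:
    """Series-corrected large-sample p-value of the Rayleigh test.

    Z = n r^2; p = exp(-Z) [1 + (2Z - Z^2)/(4n)
                              - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)],
    clamped to [0, 1].
    """
    if not (0.0 <= r <= 1.0):
        raise ValueError(f"mean vector length {r} outside [0, 1]")
    if n < 2:
        raise ValueError("need n >= 2")
    z = n * r * r
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4)
        / (288.0 * n * n)
    )
    return min(max(p, 0.0), 1.0)


def rayleigh_test(sample: CircularSample) -> RayleighResult:
    """Rayleigh test of circular uniformity (axial data are doubled)."""
    mv = mean_vector(sample)
    n = sample.n
    return RayleighResult(n, mv.mu, mv.r, n * mv.r**2,
                          rayleigh_p(n, mv.r), axial=sample.axial)


# ---------------------------------------------------------------- Watson U2

def _u2_from_counts(za: np.ndarray, n: int, m: int,
                    group_sizes: np.ndarray) -> np.ndarray:
    """Tie-weighted two-sample U2 from sorted membership indicators.

    ``za``: (P, N) 0/1 matrix (1 = sample a), columns in combined sorted
    order; ``group_sizes``: multiplicities of the distinct sorted values
    (so identical samples give exactly U2 = 0).
    """
    bounds = np.cumsum(group_sizes) - 1          # last index of each group
    ca = np.cumsum(za, axis=1)[:, bounds]        # a-counts up to each value
    ct = np.cumsum(group_sizes)                  # total counts
    d = ca / n - (ct[None, :] - ca) / m
    w = group_sizes / (n + m)
    dbar = d @ w
    return (n * m) / (n + m) ** 2 * ((d - dbar[:, None]) ** 2 @ group_sizes)


def watson_u2_stat(a_deg, b_deg, axial: bool = False) -> float:
    """Two-sample Watson U-squared statistic (tie-weighted)."""
    a = np.asarray(a_deg, float) % 360.0
    b = np.asarray(b_deg, float) % 360.0
    if axial:
        a, b = (2 * a) % 360.0, (2 * b) % 360.0
    n, m = len(a), len(b)
    values = np.concatenate([a, b])
    labels = np.concatenate([np.ones(n, int), np.zeros(m, int)])
    order = np.argsort(values, kind="stable")
    v, z = values[order], labels[order]
    _, sizes = np.unique(v, return_counts=True)
    return float(_u2_from_counts(z[None, :], n, m, sizes)[0])


def watson_u2_asymptotic_p(u2: float, terms: int = 50) -> float:
    """Asymptotic tail probability P(U2 > u2)."""
    if u2 <= 0.0:
        return 1.0
    k = np.arange(1, terms + 1)
    p = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * np.pi**2 * u2))
    return float(min(max(p, 0.0), 1.0))


def _critical_values() -> list[tuple[float, float]]:
    """(alpha, critical U2) pairs from the asymptotic distribution."""
    alphas = [0.001, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5]
    return [(a, brentq(lambda u, a=a: watson_u2_asymptotic_p(u) - a,
                       1e-4, 5.0)) for a in alphas]


_CRITICAL = None


def watson_u2_bound(u2: float) -> str:
    """Table-style significance bound, e.g. "<0.05" or ">0.5"."""
    global _CRITICAL
    if _CRITICAL is None:
        _CRITICAL = _critical_values()
    for alpha, crit in _CRITICAL:               # ascending alpha
        if u2 >= crit:
            return f"<{alpha}"
    return ">0.5"


def watson_u2(sample_a: CircularSample, sample_b: CircularSample,
              permutations: int = 0, seed: int | None = None) -> WatsonResult:
    """Two-sample Watson U-squared test.

    Reports the statistic, a critical-value-table bound, the asymptotic
    p, and (when ``permutations`` > 0) an exact label-permutation p.
    """
    if sample_a.axial != sample_b.axial:
        raise ValueError("cannot compare axial with angular samples")
    axial = sample_a.axial
    a, b = sample_a.bearings, sample_b.bearings
    u2 = watson_u2_stat(a, b, axial=axial)
    p_perm = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        aw = (2 * a) % 360.0 if axial else a
        bw = (2 * b) % 360.0 if axial else b
        n, m = len(aw), len(bw)
        values = np.concatenate([aw, bw])
        order = np.argsort(values, kind="stable")
        v = values[order]
        _, sizes = np.unique(v, return_counts=True)
        base = np.concatenate([np.ones(n, int), np.zeros(m, int)])
        shuffles = np.argsort(rng.random((permutations, n + m)), axis=1)
        perms = base[shuffles]
        stats = _u2_from_counts(perms, n, m, sizes)
        p_perm = float((np.sum(stats >= u2 - 1e-12) + 1)
                       / (permutations + 1))
    return WatsonResult(u2, watson_u2_bound(u2),
                        watson_u2_asymptotic_p(u2), p_perm)


# ------------------------------------------------------------- bootstrap CI

def circular_ci(sample: CircularSample, level: float = 0.95,
                resamples: int = 10_000, seed: int | None = None
                ) -> tuple[float, float]:
    """Bootstrap percentile arc for the mean direction (axis if axial).

    Resamples the bearings with replacement, recomputes the mean
    direction, and takes the central ``level`` arc of the deviations
    around the point estimate.  Undefined when r = 0.
    """
    mv = mean_vector(sample)
    if mv.r <= 1e-12:
        raise ValueError("confidence arc undefined for r = 0")
    rng = np.random.default_rng(seed)
    work = np.degrees(_working_angles(sample))   # doubled if axial
    mu_w = (2.0 * mv.mu) if sample.axial else mv.mu
    n = sample.n
    draws = rng.integers(0, n, size=(resamples, n))
    a = np.radians(work[draws])
    mus = np.degrees(np.arctan2(np.sin(a).mean(axis=1),
                                np.cos(a).mean(axis=1)))
    dev = (mus - mu_w + 180.0) % 360.0 - 180.0
    if sample.axial:
        dev = dev / 2.0
    lo, hi = np.quantile(dev, [(1 - level) / 2, (1 + level) / 2])
    period = 180.0 if sample.axial else 360.0
    return (float((mv.mu + lo) % period), float((mv.mu + hi) % period))


def dog_level_means(per_dog: Mapping[str, np.ndarray],
                    axial: bool = False) -> CircularSample:
    """Reduce per-excursion bearings to one mean direction per dog.

    Dogs whose within-dog mean vector has r = 0 (perfectly cancelling
    bearings) have no defined mean and are excluded with a log entry.
    """
    means = []
    for dog, bearings in per_dog.items():
        sub = CircularSample(np.atleast_1d(bearings), axial=axial)
        mv = mean_vector(sub)
        if mv.r <= 1e-12:
            logger.warning("dog %s: r = 0 at dog level; excluded", dog)
            continue
        means.append(mv.mu)
    return CircularSample(np.asarray(means), axial=axial, level="dog")


def rose_bins(bearings, width_deg: float = 5.0) -> np.ndarray:
    """Counts per rose-diagram bin (display only; analyses use full
    resolution).  Bin k covers [k*width, (k+1)*width)."""
    b = np.asarray(bearings, float) % 360.0
    edges = np.arange(0.0, 360.0 + width_deg, width_deg)
    counts, _ = np.histogram(b, bins=edges)
    return counts
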