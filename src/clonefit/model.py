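"""Stochastic birth-death model of clonal dynamics in the HSPC pool.

A mutant clone of hematopoietic stem/progenitor cells (HSPCs) gains or
loses cells through symmetric divisions.  Fitness ``s`` biases the clone
toward self-renewal: per cell, births occur at rate ``b = lambda_div + s``
and deaths (symmetric differentiation) at rate ``d = lambda_div``, so the
mean clone size grows as ``n1 * exp(s * dt)``.  Conditioned on an observed
size, the finite-time law is well approximated by a negative binomial
matching the exact mean and variance of the linear birth-death process.

A heterozygous clone of ``n`` cells in a pool with ``N_w`` wild-type cells
is seen in blood at variant allele frequency ``v = n / (2 (N_w + sum_n))``,
which saturates at 0.5.  Read sampling at a sequenced locus is binomial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CloneDynamicsParams",
    "CloneSizeDistribution",
    "conditional_clone_distribution",
    "vaf_from_counts",
    "sampling_loglik",
    "deterministic_vaf",
    "fit_t0_mle",
]


@dataclass(frozen=True)
class CloneDynamicsParams:
    """Parameters of the birth-death clone model.

    Parameters
    ----------
    s
        Fitness: self-renewal bias of symmetric divisions, per year.
        ``s = 0`` is neutral drift; negative values down to ``-lambda_div``
        are allowed for model-comparison purposes.
    lambda_div
        Symmetric-division (and death) rate per cell per year.
    n_w
        Average number of wild-type HSPCs in the individual.
    """

    s: float
    lambda_div: float = 1.0
    n_w: float = 1e5

    def __post_init__(self) -> None:
        if self.lambda_div <= 0:
            raise ValueError(f"lambda_div must be > 0, got {self.lambda_div}")
        if self.n_w < 1:
            raise ValueError(f"n_w must be >= 1, got {self.n_w}")
        if self.s < -self.lambda_div:
            raise ValueError(
                f"s={self.s} implies a negative birth rate (s < -lambda_div)"
            )

    @property
    def birth_rate(self) -> float:
        return self.lambda_div + self.s

    @property
    def death_rate(self) -> float:
        return self.lambda_div


@dataclass(frozen=True)
class CloneSizeDistribution:
    """Approximate distribution of a clone's size after an elapsed time."""

    mean: float
    variance: float
    family: str  # "negative_binomial" | "poisson_fallback" | "point_mass"
    r: float | None = None  # NB shape, mean^2 / (variance - mean)
    p: float | None = None  # NB success prob, mean / variance

    def logpmf(self, k) -> np.ndarray:
        k = np.asarray(k)
        if self.family == "point_mass":
            return np.where(k == round(self.mean), 0.0, -np.inf)
        if self.family == "poisson_fallback":
            return stats.poisson.logpmf(k, self.mean)
        return stats.nbinom.logpmf(k, self.r, self.p)

    def cdf(self, k) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        if self.family == "point_mass":
            return np.where(k >= round(self.mean), 1.0, 0.0)
        if self.family == "poisson_fallback":
            return stats.poisson.cdf(k, self.mean)
        return stats.nbinom.cdf(k, self.r, self.p)


def _bd_moments(n1: float, s: float, lambda_div: float, dt: float) -> tuple[float, float]:
    """Exact conditional mean and variance of the linear birth-death process."""
    if s == 0.0:
        return float(n1), float(2.0 * lambda_div * n1 * dt)
    growth = math.exp(s * dt)
    mean = n1 * growth
    variance = n1 * ((2.0 * lambda_div + s) / s) * growth * (growth - 1.0)
    return float(mean), float(variance)


def conditional_clone_distribution(
    n1: float, params: CloneDynamicsParams, dt: float
) -> CloneSizeDistribution:
    """Distribution of clone size after ``dt`` years given current size ``n1``.

    Mean is ``n1 * exp(s dt)``; the variance is that of the linear
    birth-death process with rates ``b = lambda + s``, ``d = lambda``:
    ``n1 ((b+d)/s) e^{s dt}(e^{s dt} - 1)``, with continuity limit
    ``2 lambda n1 dt`` at ``s = 0``.  A negative binomial is moment-matched
    whenever over-dispersed; for very short intervals (variance <= mean)
    a Poisson of the same mean is used, and ``dt = 0`` or ``n1 = 0`` give
    a point mass.
    """
    if n1 < 0:
        raise ValueError(f"n1 must be >= 0, got {n1}")
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if dt == 0 or n1 == 0:
        return CloneSizeDistribution(mean=float(n1), variance=0.0, family="point_mass")
    mean, variance = _bd_moments(n1, params.s, params.lambda_div, dt)
    if variance > mean:
        r = mean**2 / (variance - mean)
        p = mean / variance
        return CloneSizeDistribution(mean=mean, variance=variance,
                                     family="negative_binomial", r=r, p=p)
    return CloneSizeDistribution(mean=mean, variance=mean, family="poisson_fallback")


def vaf_from_counts(clone_sizes, n_w: float) -> np.ndarray:
    """Map clone sizes to VAFs under the shared diploid HSPC pool.

    ``v_i = n_i / (2 (N_w + sum_j n_j))``; clones are mutually exclusive
    (each cell carries at most one of the clone-defining variants).
    """
    sizes = np.asarray(clone_sizes, dtype=float)
    if np.any(sizes < 0):
        raise ValueError("clone sizes must be non-negative")
    if n_w < 1:
        raise ValueError(f"n_w must be >= 1, got {n_w}")
    total = n_w + sizes.sum()
    return sizes / (2.0 * total)


def sampling_loglik(alt, depth, v) -> np.ndarray | float:
    """Binomial log-likelihood of ``alt`` variant reads out of ``depth`` at VAF ``v``."""
    alt_a, depth_a = np.asarray(alt), np.asarray(depth)
    if np.any(alt_a > depth_a) or np.any(alt_a < 0):
        raise ValueError("require 0 <= alt <= depth")
    out = stats.binom.logpmf(alt_a, depth_a, v)
    return float(out) if np.isscalar(alt) and np.ndim(v) == 0 else out


def deterministic_vaf(t, s: float, n_w: float, t0: float) -> np.ndarray | float:
    """Mean-field logistic VAF of a clone founded at ``t0``:
    ``v(t) = 1 / (2 + 2 N_w exp(-s (t - t0)))``.
    """
    t = np.asarray(t, dtype=float)
    out = 1.0 / (2.0 + 2.0 * n_w * np.exp(-s * (t - t0)))
    return float(out) if out.ndim == 0 else out


def fit_t0_mle(trajectory, s_map: float, n_w_map: float) -> float:
    """Maximum-likelihood acquisition time of the deterministic logistic fit.

    Display-only: anchors the MAP logistic curve to the read counts.  The
    search is bounded to ``t0 <= first observed age``.
    """
    if s_map <= 0:
        raise ValueError(f"s_map must be > 0, got {s_map}")
    ages = np.asarray(trajectory.ages, dtype=float)
    alts = np.asarray(trajectory.alt_reads)
    depths = np.asarray(trajectory.depths)

    def negloglik(t0: float) -> float:
        v = deterministic_vaf(ages, s_map, n_w_map, t0)
        return -float(np.sum(stats.binom.logpmf(alts, depths, v)))

    hi = float(ages[0])
    lo = hi - 120.0
    coarse = np.linspace(lo, hi, 2401)  # 0.05-year steps
    best = coarse[int(np.argmin([negloglik(t) for t in coarse]))]
    res = optimize.minimize_scalar(
        negloglik, bounds=(max(lo, best - 0.1), min(hi, best + 0.1)), method="bounded"
    )
    return float(res.x)
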