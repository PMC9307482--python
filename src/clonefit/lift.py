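"""LiFT: likelihood-based filtering of variant trajectories.

Each candidate trajectory is scored under two generative models:

* the clonal model — a growing (or drifting) birth-death clone observed
  through binomial read sampling, with fitness and pool size
  marginalized over their prior grids (:mod:`clonefit.inference`);
* an artifact model — a proportion that is constant over time, binomial
  for variants unique to one participant and beta-binomial (to absorb
  overdispersion of recurrent sequencing artifacts) for variants seen in
  several participants.

A trajectory is called *fit* when the clonal evidence is at least
``threshold`` times the artifact evidence (Bayes factor >= 4 by
default).  Synonymous trajectories calibrate the artifact noise
parameters and are never called fit themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import optimize, stats
from scipy.special import logsumexp

from .inference import InferenceConfig, marginal_clonal_log_evidence, merge_clone_obs
from .io import Cohort, InsufficientDataError, Trajectory

__all__ = [
    "ArtifactNoiseParams",
    "CandidateRule",
    "LiFTResult",
    "calibrate_noise",
    "artifact_evidence",
    "clonal_evidence",
    "is_fit",
    "lift_classify",
]

DEFAULT_NOISE_RHO = 0.01
DEFAULT_THETA_PRIOR = (1.0, 99.0)  # Beta with mean 1% VAF
_QUAD_ORDER = 256


@dataclass(frozen=True)
class ArtifactNoiseParams:
    """Noise model for constant-proportion artifacts.

    ``rho`` is the beta-binomial overdispersion of read counts around the
    underlying proportion theta; ``theta_a, theta_b`` parameterize the
    Beta prior on theta.
    """

    rho: float = DEFAULT_NOISE_RHO
    theta_a: float = DEFAULT_THETA_PRIOR[0]
    theta_b: float = DEFAULT_THETA_PRIOR[1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.theta_a <= 0 or self.theta_b <= 0:
            raise ValueError("theta prior hyperparameters must be > 0")


@dataclass(frozen=True)
class CandidateRule:
    """Pre-filter for LiFT scoring: >= 2 timepoints, at least one VAF > 1%."""

    min_timepoints: int = 2
    min_vaf: float = 0.01


@dataclass
class LiFTResult:
    trajectory: Trajectory
    log_ev_clonal: float
    log_ev_artifact: float
    call: str  # "fit" | "filtered"
    artifact_family: str  # "binomial" | "beta_binomial"

    @property
    def bayes_factor(self) -> float:
        with np.errstate(over="ignore"):
            return float(np.exp(self.log_ev_clonal - self.log_ev_artifact))

    def to_record(self) -> dict:
        return {
            "participant_id": self.trajectory.participant_id,
            "variant_id": self.trajectory.variant_id,
            "log_ev_clonal": self.log_ev_clonal,
            "log_ev_artifact": self.log_ev_artifact,
            "bayes_factor": self.bayes_factor,
            "call": self.call,
            "artifact_family": self.artifact_family,
        }


def _betabinom_ab(theta: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray]:
    conc = (1.0 - rho) / rho
    return theta * conc, (1.0 - theta) * conc


def calibrate_noise(synonymous_trajectories: list[Trajectory]) -> ArtifactNoiseParams:
    """Estimate artifact noise from synonymous trajectories.

    Overdispersion rho is the maximum-likelihood value of a shared
    beta-binomial across all synonymous observations, with each
    variant's underlying proportion profiled at its pooled mean VAF; the
    theta prior is moment-matched to the per-variant mean VAFs.  Fewer
    than five trajectories fall back to the documented defaults.
    """
    if len(synonymous_trajectories) < 5:
        warnings.warn(
            "fewer than 5 synonymous trajectories; using default noise parameters"
        )
        return ArtifactNoiseParams()

    by_variant: dict[str, list[Trajectory]] = {}
    for t in synonymous_trajectories:
        by_variant.setdefault(t.variant_id, []).append(t)
    obs, theta_hat = [], []
    for vid, trajs in sorted(by_variant.items()):
        alts = np.concatenate([t.alt_reads for t in trajs])
        depths = np.concatenate([t.depths for t in trajs])
        th = float(alts.sum()) / float(depths.sum()) if depths.sum() else 0.0
        th = min(max(th, 1e-6), 0.5)
        obs.append((alts, depths, th))
        theta_hat.append(th)

    def negloglik(log_rho: float) -> float:
        rho = float(np.exp(log_rho))
        total = 0.0
        for alts, depths, th in obs:
            a, b = _betabinom_ab(np.array(th), rho)
            total -= float(np.sum(stats.betabinom.logpmf(alts, depths, a, b)))
        return total

    res = optimize.minimize_scalar(
        negloglik, bounds=(np.log(1e-8), np.log(0.9)), method="bounded"
    )
    rho = float(np.exp(res.x))

    m = float(np.mean(theta_hat))
    v = float(np.var(theta_hat))
    if v > 0 and v < m * (1.0 - m):
        k = m * (1.0 - m) / v - 1.0
        theta_a, theta_b = m * k, (1.0 - m) * k
    else:  # degenerate spread: keep the mean, moderate concentration
        theta_a, theta_b = m * 100.0, (1.0 - m) * 100.0
    return ArtifactNoiseParams(rho=rho, theta_a=theta_a, theta_b=theta_b)


def artifact_evidence(
    trajectory: Trajectory, noise: ArtifactNoiseParams, family: str
) -> float:
    """Log evidence of the constant-proportion artifact model.

    Marginalizes theta over its Beta prior with fixed-order
    Gauss-Legendre quadrature on (0, 1); reads are binomial
    (``family="binomial"``) or beta-binomial with overdispersion
    ``noise.rho`` (``family="beta_binomial"``).
    """
    if family not in ("binomial", "beta_binomial"):
        raise ValueError(f"unknown artifact family {family!r}")
    pts = [p for p in trajectory.points if p.depth > 0]
    if len(pts) < len(trajectory.points):
        warnings.warn("skipping zero-depth timepoints in artifact evidence")
    alts = np.array([p.alt_reads for p in pts])
    depths = np.array([p.depth for p in pts])

    x, w = leggauss(_QUAD_ORDER)
    theta = 0.5 * (x + 1.0)
    logw = np.log(0.5 * w)
    log_prior = stats.beta.logpdf(theta, noise.theta_a, noise.theta_b)
    if family == "beta_binomial" and noise.rho > 0:
        a, b = _betabinom_ab(theta, noise.rho)
        loglik = stats.betabinom.logpmf(
            alts[:, None], depths[:, None], a[None, :], b[None, :]
        ).sum(axis=0)
    else:
        loglik = stats.binom.logpmf(alts[:, None], depths[:, None], theta[None, :]).sum(axis=0)
    return float(logsumexp(loglik + log_prior + logw))


def clonal_evidence(
    trajectory: Trajectory, config: InferenceConfig | None = None
) -> float:
    """Log evidence of the single-clone birth-death model for one trajectory."""
    if len(trajectory) < 2:
        raise InsufficientDataError("clonal evidence needs >= 2 timepoints")
    config = config or InferenceConfig()
    ages, reads = merge_clone_obs([trajectory])
    return marginal_clonal_log_evidence(ages, reads, config)


def is_fit(log_ev_clonal: float, log_ev_artifact: float, threshold: float = 4.0) -> bool:
    """Fit call rule: clonal evidence at least ``threshold`` times the
    artifact evidence (inclusive)."""
    return bool(log_ev_clonal - log_ev_artifact >= np.log(threshold) - 1e-12)


def lift_classify(
    cohort: Cohort,
    threshold: float = 4.0,
    candidate_rule: CandidateRule | None = None,
    noise: ArtifactNoiseParams | None = None,
    config: InferenceConfig | None = None,
) -> list[LiFTResult]:
    """Score candidate trajectories and call each fit or filtered.

    Candidates have at least ``min_timepoints`` waves and one VAF above
    ``min_vaf``; the artifact family is beta-binomial for recurrent
    variants and binomial otherwise; a trajectory is fit iff its Bayes
    factor (clonal vs artifact evidence) is >= ``threshold``.
    Synonymous trajectories are scored but never called fit.
    """
    rule = candidate_rule or CandidateRule()
    config = config or InferenceConfig()
    if noise is None:
        noise = calibrate_noise(cohort.synonymous())
    results = []
    for t in cohort:
        if len(t) < rule.min_timepoints or t.max_vaf <= rule.min_vaf:
            continue
        family = "beta_binomial" if t.recurrent else "binomial"
        log_art = artifact_evidence(t, noise, family)
        log_clo = clonal_evidence(t, config)
        fit = is_fit(log_clo, log_art, threshold) and not t.annotation.is_synonymous
        call = "fit" if fit else "filtered"
        results.append(LiFTResult(t, log_clo, log_art, call, family))
    return results


def results_frame(results: list[LiFTResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_record() for r in results])
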