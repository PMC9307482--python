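"""Seeded synthetic-cohort generators and the exact birth-death simulators.

Two simulators of the same continuous-time linear birth-death process
(per-cell birth rate ``b = lambda + s``, death rate ``d = lambda``):

* :func:`simulate_clone` — event-driven Gillespie sample paths, the
  reference oracle for the moment-matched negative-binomial transition.
* :func:`sample_bd_transition` — draws from the exact finite-time law
  (each founder lineage survives with probability ``1 - alpha`` and, if
  surviving, has geometric size), used for cohort-scale generation.

:func:`simulate_cohort` emulates the design of a longitudinal aging
cohort: 2-5 sampling waves roughly three years apart at ages 70-92,
targeted sequencing around 2000x depth, expanding clones with fitness up
to ~0.4/yr, plus flat recurrent-artifact and synonymous trajectories for
noise calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Cohort, TimepointObs, Trajectory, VariantAnnotation, _set_recurrence
from .model import vaf_from_counts

__all__ = [
    "CloneSpec",
    "DepthModel",
    "SimScenario",
    "simulate_clone",
    "sample_bd_transition",
    "simulate_reads",
    "simulate_cohort",
]


def simulate_clone(s, lambda_div, n0, t_grid, seed, n_reps: int = 1) -> np.ndarray:
    """Exact Gillespie birth-death paths recorded at ``t_grid``.

    Returns an ``(n_reps, len(t_grid))`` integer array of clone sizes;
    zero is absorbing.  ``t_grid`` is relative to the start (``t=0`` holds
    ``n0``).  Vectorized lock-step over replicates, pure numpy.
    """
    b, d = lambda_div + s, lambda_div
    if b < 0 or d < 0:
        raise ValueError("rates must be non-negative (need s >= -lambda_div)")
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    n = np.full(n_reps, int(n0), dtype=np.int64)
    t = np.zeros(n_reps)
    out = np.zeros((n_reps, len(t_grid)), dtype=np.int64)
    nxt = np.zeros(n_reps, dtype=np.int64)  # next grid index to record
    total_rate = b + d
    p_birth = b / total_rate if total_rate > 0 else 0.0

    while True:
        active = nxt < len(t_grid)
        if not active.any():
            break
        rate = total_rate * n
        with np.errstate(divide="ignore"):
            wait = np.where(rate > 0, rng.exponential(size=n_reps) / np.maximum(rate, 1e-300), np.inf)
        t_new = t + wait
        # record all grid times passed before the next event, at the old size
        while True:
            idx = np.minimum(nxt, len(t_grid) - 1)
            rec = active & (t_grid[idx] <= t_new)
            if not rec.any():
                break
            out[rec, nxt[rec]] = n[rec]
            nxt[rec] += 1
            active = nxt < len(t_grid)
        step = active & np.isfinite(t_new)
        births = rng.random(n_reps) < p_birth
        n[step & births] += 1
        n[step & ~births] -= 1
        t = np.where(step, t_new, t)
    return out


def sample_bd_transition(n1, s, lambda_div, dt, rng, size=None) -> np.ndarray:
    """Exact draw of clone size after ``dt`` years given current size ``n1``.

    Uses the closed-form lineage representation of the linear birth-death
    process: each of the ``n1`` founder cells leaves zero descendants with
    probability ``alpha`` and otherwise a geometric number; the survivors'
    total is binomial + negative binomial.  Distributionally identical to
    Gillespie simulation but O(1) per draw.
    """
    b, d = lambda_div + s, lambda_div
    if dt == 0:
        return np.full(size, n1, dtype=np.int64) if size else np.int64(n1)
    if s == 0.0:
        alpha = beta = b * dt / (1.0 + b * dt)
    else:
        e = np.exp(s * dt)
        alpha = d * (e - 1.0) / (b * e - d)
        beta = b * (e - 1.0) / (b * e - d)
    surv = rng.binomial(int(n1), 1.0 - alpha, size=size)
    surv_arr = np.atleast_1d(surv)
    extra = np.zeros_like(surv_arr)
    pos = surv_arr > 0
    if pos.any():
        extra[pos] = rng.negative_binomial(surv_arr[pos], 1.0 - beta)
    total = surv_arr + extra
    return total if size else total[0]


@dataclass(frozen=True)
class DepthModel:
    """Sequencing depth drawn from a negative binomial (mean ~2000x,
    CV ~0.3 emulating targeted error-corrected panels)."""

    mean: float = 2000.0
    cv: float = 0.3

    def draw(self, rng, size=None):
        var = (self.cv * self.mean) ** 2
        if var <= self.mean:
            return rng.poisson(self.mean, size=size)
        r = self.mean**2 / (var - self.mean)
        p = self.mean / var
        return rng.negative_binomial(r, p, size=size)


def simulate_reads(v, depth_model: DepthModel, rng, rho: float = 0.0):
    """Draw ``(depth, alt_reads)`` at VAF ``v``.

    ``rho = 0`` gives pure binomial read sampling; ``rho > 0`` draws the
    per-sample proportion from a Beta with mean ``v`` and overdispersion
    ``rho`` (beta-binomial reads, emulating recurrent artifacts).
    """
    if not 0.0 <= v <= 0.5 + 1e-12:
        raise ValueError(f"v must lie in [0, 0.5], got {v}")
    depth = int(depth_model.draw(rng))
    if v == 0.0:
        return depth, 0
    if rho > 0.0:
        conc = (1.0 - rho) / rho
        p = rng.beta(v * conc, (1.0 - v) * conc)
    else:
        p = v
    return depth, int(rng.binomial(depth, p))


@dataclass(frozen=True)
class CloneSpec:
    """One simulated clone: fitness, size at the first wave, member variants.

    Clones sharing a ``participant`` label compete in one HSPC pool.
    """

    s: float
    v0: float  # VAF at the first sampled wave (clone seeded there, not at t0)
    n_variants: int = 1
    gene: str = "DNMT3A"
    participant: str | None = None


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for a synthetic longitudinal cohort."""

    seed: int
    n_w: float = 1e5
    lambda_div: float = 1.0
    clones: tuple[CloneSpec, ...] = ()
    waves: tuple[float, ...] = (70.0, 73.0, 76.0, 79.0, 82.0)
    depth_model: DepthModel = field(default_factory=DepthModel)
    n_artifacts: int = 0
    artifact_rho: float = 0.02
    artifact_theta_range: tuple[float, float] = (0.005, 0.03)
    n_artifact_loci: int = 8
    n_synonymous: int = 0
    synonymous_theta_range: tuple[float, float] = (0.001, 0.01)
    n_synonymous_loci: int = 6

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.waves, self.waves[1:])):
            raise ValueError("waves must be strictly increasing")
        if self.lambda_div <= 0 or self.n_w < 1:
            raise ValueError("rates and pool size must be positive")


def _clone_sizes(spec: CloneSpec, scenario: SimScenario, rng) -> np.ndarray:
    n0 = max(1, round(2 * scenario.n_w * spec.v0 / (1 - 2 * spec.v0)))
    sizes = [n0]
    for dt in np.diff(scenario.waves):
        sizes.append(int(sample_bd_transition(sizes[-1], spec.s, scenario.lambda_div, dt, rng)))
    return np.array(sizes, dtype=np.int64)


def simulate_cohort(scenario: SimScenario) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort plus a truth table for scoring.

    One participant per clone entry (multi-variant clones share one latent
    size path and a participant); artifact and synonymous trajectories get
    their own participants and draw variant ids from small locus pools so
    that recurrence (and hence the beta-binomial artifact model) arises.
    Truth columns: participant_id, variant_id, clone_id, kind
    (clone|artifact|synonymous), true_s, theta, seeded_at_first_wave.
    """
    rng = np.random.default_rng(scenario.seed)
    waves = np.asarray(scenario.waves)
    trajectories: list[Trajectory] = []
    truth_rows: list[dict] = []

    # --- driver clones; clones sharing a participant label share one pool
    by_pid: dict[str, list[tuple[int, CloneSpec]]] = {}
    for ci, spec in enumerate(scenario.clones):
        pid = spec.participant or f"P{ci:03d}"
        by_pid.setdefault(pid, []).append((ci, spec))
    for pid, members in by_pid.items():
        size_paths = np.stack([_clone_sizes(spec, scenario, rng) for _, spec in members])
        vaf_paths = np.stack([
            vaf_from_counts(size_paths[:, wi], scenario.n_w) for wi in range(len(waves))
        ]).T  # (clone, wave)
        for (ci, spec), vafs in zip(members, vaf_paths):
            for vi in range(spec.n_variants):
                vid = f"chr1:{1000 + 10 * ci + vi}:A:G"
                points = []
                for age, v in zip(waves, vafs):
                    depth, alt = simulate_reads(float(v), scenario.depth_model, rng)
                    points.append(TimepointObs(age=float(age), depth=depth, alt_reads=alt,
                                               unique_alt_reads=min(alt, max(0, alt - 1))))
                ann = VariantAnnotation(gene=spec.gene, protein_change=f"X{ci}{vi}Y",
                                        consequence="missense", gnomad_p=0.01)
                trajectories.append(Trajectory(pid, vid, ann, points))
                truth_rows.append({
                    "participant_id": pid, "variant_id": vid, "clone_id": f"C{ci:03d}",
                    "kind": "clone", "true_s": spec.s, "theta": np.nan,
                    "seeded_at_first_wave": True,
                })

    # --- flat artifact trajectories (recurrent loci, beta-binomial reads)
    lo, hi = scenario.artifact_theta_range
    art_thetas = np.exp(rng.uniform(np.log(lo), np.log(hi), scenario.n_artifact_loci))
    for ai in range(scenario.n_artifacts):
        pid = f"A{ai:03d}"
        locus = int(rng.integers(scenario.n_artifact_loci))
        vid = f"chr2:{5000 + locus}:C:T"
        theta = float(art_thetas[locus])
        points = []
        for age in waves:
            depth, alt = simulate_reads(theta, scenario.depth_model, rng,
                                        rho=scenario.artifact_rho)
            points.append(TimepointObs(age=float(age), depth=depth, alt_reads=alt,
                                       unique_alt_reads=min(alt, max(0, alt - 1))))
        ann = VariantAnnotation(gene="ARTI1", protein_change=f"A{locus}B",
                                consequence="missense", gnomad_p=0.01)
        trajectories.append(Trajectory(pid, vid, ann, points))
        truth_rows.append({
            "participant_id": pid, "variant_id": vid, "clone_id": "",
            "kind": "artifact", "true_s": 0.0, "theta": theta,
            "seeded_at_first_wave": False,
        })

    # --- synonymous trajectories (noise calibration set)
    lo, hi = scenario.synonymous_theta_range
    syn_thetas = np.exp(rng.uniform(np.log(lo), np.log(hi), scenario.n_synonymous_loci))
    for si in range(scenario.n_synonymous):
        pid = f"S{si:03d}"
        locus = int(rng.integers(scenario.n_synonymous_loci))
        vid = f"chr3:{9000 + locus}:G:A"
        theta = float(syn_thetas[locus])
        points = []
        for age in waves:
            depth, alt = simulate_reads(theta, scenario.depth_model, rng,
                                        rho=scenario.artifact_rho)
            points.append(TimepointObs(age=float(age), depth=depth, alt_reads=alt,
                                       unique_alt_reads=min(alt, max(0, alt - 1))))
        ann = VariantAnnotation(gene="SYN1", protein_change=f"S{locus}S",
                                consequence="synonymous", gnomad_p=0.01)
        trajectories.append(Trajectory(pid, vid, ann, points))
        truth_rows.append({
            "participant_id": pid, "variant_id": vid, "clone_id": "",
            "kind": "synonymous", "true_s": 0.0, "theta": theta,
            "seeded_at_first_wave": False,
        })

    _set_recurrence(trajectories)
    truth = pd.DataFrame(truth_rows, columns=[
        "participant_id", "variant_id", "clone_id", "kind", "true_s",
        "theta", "seeded_at_first_wave",
    ])
    cohort = Cohort(trajectories, provenance=f"simulated (seed={scenario.seed})")
    return cohort, truth
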