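"""Clonal-structure selection by Bayesian model comparison.

Which of an individual's fit variants ride on the same clone?  Every set
partition of the variant ids is a candidate structure: variants in one
block share a single latent clone-size trajectory (their reads are
emitted from one hidden path), and all clones share the wild-type pool
size ``N_w``.  Structures are scored by marginal likelihood plus a prior
penalty of ``log(kappa)`` per co-occurrence merge, encoding that
multi-mutation clones are rarer than independent clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .inference import InferenceConfig, clone_loglik_grid, merge_clone_obs
from .io import Trajectory, ValidationError

__all__ = [
    "ClonalStructure",
    "StructureSelection",
    "enumerate_structures",
    "structure_log_evidence",
    "select_structure",
]


@dataclass(frozen=True)
class ClonalStructure:
    """A set partition of one participant's fit variants into clones."""

    participant_id: str
    partition: tuple[frozenset, ...]
    prior_log_weight: float = 0.0

    @property
    def n_clones(self) -> int:
        return len(self.partition)

    @property
    def n_merges(self) -> int:
        return sum(len(c) for c in self.partition) - len(self.partition)

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "partition": [sorted(c) for c in self.partition],
            "prior_log_weight": self.prior_log_weight,
        }


@dataclass
class StructureSelection:
    best: ClonalStructure
    candidates: list[ClonalStructure]
    log_evidences: list[float]
    log_evidence_vs_independent: float

    def to_dict(self) -> dict:
        return {
            "best": self.best.to_dict(),
            "candidates": [
                dict(c.to_dict(), log_evidence=e)
                for c, e in zip(self.candidates, self.log_evidences)
            ],
            "log_evidence_vs_independent": self.log_evidence_vs_independent,
        }


def _set_partitions(items: list):
    """Yield all set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def enumerate_structures(
    variant_ids, max_variants: int = 8, kappa: float = 0.5,
    participant_id: str = "",
) -> list[ClonalStructure]:
    """All candidate partitions of ``variant_ids`` with merge penalties.

    ``prior_log_weight = log(kappa) * (#variants - #clones)``; kappa = 0
    forbids merges entirely.  Raises when the variant count exceeds
    ``max_variants`` (Bell-number blow-up: pre-group or raise the cap).
    """
    vids = sorted(variant_ids)
    if len(vids) > max_variants:
        raise ValueError(
            f"{len(vids)} variants exceed max_variants={max_variants}; "
            "pre-cluster the variants or raise the cap"
        )
    log_kappa = np.log(kappa) if kappa > 0 else -np.inf
    out = []
    for part in _set_partitions(vids):
        merges = len(vids) - len(part)
        weight = 0.0 if merges == 0 else float(log_kappa * merges)
        out.append(ClonalStructure(
            participant_id=participant_id,
            partition=tuple(sorted((frozenset(c) for c in part), key=sorted)),
            prior_log_weight=weight,
        ))
    return out


def structure_log_evidence(
    trajectories: list[Trajectory],
    structure: ClonalStructure,
    config: InferenceConfig | None = None,
    _subset_cache: dict | None = None,
) -> float:
    """Marginal likelihood of one candidate structure.

    Clones are conditionally independent given the shared pool size, so
    the evidence is the N_w-prior-weighted product of per-clone
    s-marginalized likelihoods.
    """
    config = config or InferenceConfig()
    by_vid = {t.variant_id: t for t in trajectories}
    covered = set().union(*structure.partition) if structure.partition else set()
    if covered != set(by_vid):
        raise ValidationError("structure is not a partition of the individual's variants")

    log_s, log_nw = config.log_s_prior, config.log_nw_prior
    total = log_nw.copy()
    for clone in structure.partition:
        key = frozenset(clone)
        if _subset_cache is not None and key in _subset_cache:
            logM = _subset_cache[key]
        else:
            ages, reads = merge_clone_obs([by_vid[v] for v in sorted(clone)])
            L = clone_loglik_grid(ages, reads, config)
            logM = logsumexp(L + log_s[:, None], axis=0)  # (NW,)
            if _subset_cache is not None:
                _subset_cache[key] = logM
        total = total + logM
    return float(logsumexp(total))


def select_structure(
    trajectories: list[Trajectory],
    config: InferenceConfig | None = None,
    kappa: float = 0.5,
    max_variants: int = 8,
) -> StructureSelection:
    """Pick the maximum-posterior clonal structure for one individual.

    Ties are broken toward more clones (fewer merges); the selection
    reports the best structure's evidence relative to the all-singletons
    structure.
    """
    config = config or InferenceConfig()
    if not trajectories:
        raise ValueError("select_structure needs at least one trajectory")
    pid = trajectories[0].participant_id
    candidates = enumerate_structures(
        {t.variant_id for t in trajectories}, max_variants, kappa, pid
    )
    cache: dict = {}
    evidences = [
        structure_log_evidence(trajectories, c, config, _subset_cache=cache)
        for c in candidates
    ]
    scores = [e + c.prior_log_weight for c, e in zip(candidates, evidences)]
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-scores[i], candidates[i].n_merges),
    )
    best_i = order[0]
    singleton_i = next(i for i, c in enumerate(candidates) if c.n_merges == 0)
    return StructureSelection(
        best=candidates[best_i],
        candidates=candidates,
        log_evidences=evidences,
        log_evidence_vs_independent=evidences[best_i] - evidences[singleton_i],
    )
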