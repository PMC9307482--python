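"""End-to-end orchestration: validate -> QC -> (threshold | LiFT) ->
clonal structure -> fitness inference -> gene table, with a run manifest.

Every stage output is a pure function of (input, config); rerunning with
the same manifest reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import (InferenceConfig, gene_fitness_table, infer_posterior)
from .io import (Cohort, QCRules, chip_threshold_filter, qc_filter, read_cohort,
                 vaf_gradient, write_results)
from .lift import CandidateRule, calibrate_noise, lift_classify, results_frame
from .structure import select_structure

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    input_path: str
    output_dir: str
    qc: QCRules = field(default_factory=QCRules)
    candidate_rule: CandidateRule = field(default_factory=CandidateRule)
    bf_threshold: float = 4.0
    vaf_threshold: float = 0.02
    min_timepoints: int = 2
    kappa: float = 0.5
    max_variants_per_individual: int = 8
    use_coarse_grids: bool = False
    min_gene_fitness: float = 0.02
    seed: int = 0
    log_level: str = "INFO"

    def inference_config(self) -> InferenceConfig:
        return InferenceConfig.coarse() if self.use_coarse_grids else InferenceConfig()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw:
            raw["qc"] = QCRules(**raw["qc"])
        if "candidate_rule" in raw:
            raw["candidate_rule"] = CandidateRule(**raw["candidate_rule"])
        return cls(**raw)

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["clonefit_version"] = __version__
        return d


def _growing_fraction(trajectories) -> float:
    grads = [vaf_gradient(t) for t in trajectories if len(t) >= 2]
    return float(np.mean([g > 0 for g in grads])) if grads else float("nan")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; writes lift.tsv, structures.json,
    fitness.json, genes.tsv, report.json and manifest.json to the output
    directory and returns the report dict."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    icfg = config.inference_config()

    cohort = read_cohort(config.input_path)
    logger.info("read %d trajectories", len(cohort))
    cohort, rejections = qc_filter(cohort, config.qc)
    logger.info("QC kept %d trajectories (%d rejected)", len(cohort), len(rejections))

    thresholded = chip_threshold_filter(
        cohort, config.vaf_threshold, config.min_timepoints
    )

    noise = calibrate_noise(cohort.synonymous())
    results = lift_classify(
        cohort, config.bf_threshold, config.candidate_rule, noise, icfg
    )
    fit = [r.trajectory for r in results if r.call == "fit"]
    write_results(results_frame(results), out / "lift.tsv", "tsv")

    structures, posteriors, gene_of = {}, [], {}
    for pid, trajs in sorted(Cohort(fit).participants.items()):
        sel = select_structure(
            trajs, icfg, config.kappa, config.max_variants_per_individual
        )
        structures[pid] = sel.to_dict()
        posteriors.extend(infer_posterior(trajs, sel.best.partition, icfg))
        gene_of.update({t.variant_id: t.annotation.gene for t in trajs})
    write_results(structures, out / "structures.json", "json")
    write_results({
        "posteriors": [p.to_dict() for p in posteriors]
    }, out / "fitness.json", "json")

    if posteriors:
        genes = gene_fitness_table(posteriors, gene_of)
        write_results(genes, out / "genes.tsv", "tsv")
    else:
        genes = pd.DataFrame()

    n_candidates = len(results)
    report = {
        "n_input": len(cohort) + len(rejections),
        "n_qc_rejected": len(rejections),
        "n_thresholded": len(thresholded),
        "n_candidates": n_candidates,
        "n_fit": len(fit),
        "n_filtered": n_candidates - len(fit),
        "growing_fraction_fit": _growing_fraction(fit),
        "growing_fraction_thresholded": _growing_fraction(thresholded),
        "noise": {"rho": noise.rho, "theta_a": noise.theta_a, "theta_b": noise.theta_b},
        # via to_json so undefined IQRs serialize as null, not NaN
        "genes": json.loads(genes.to_json(orient="records")) if len(genes) else [],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    with open(out / "manifest.json", "w") as fh:
        json.dump(config.to_manifest(), fh, indent=1)
    return report
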