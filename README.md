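# clonefit

Fitness inference and artifact filtering for longitudinal
clonal-hematopoiesis (CHIP) variant trajectories.

Somatic driver mutations in blood stem cells found clones whose variant
allele frequency (VAF) can be tracked across repeated sequencing waves
in aging cohorts. Two questions follow from such data. Which
low-frequency trajectories are real clones rather than recurrent
sequencing artifacts? And how fast is each clone expanding — its
fitness — which is what matters for clinical monitoring?

`clonefit` answers both with one stochastic model. A clone of `n(t)`
stem cells evolves as a linear birth–death process with birth rate
`λ + s` and death rate `λ` per cell, so its mean size grows as
`e^{s·t}`; the fitness `s` (per year) is the self-renewal bias of
symmetric divisions. A heterozygous clone among `N_w` wild-type cells
is seen at VAF `v = n / (2(N_w + Σ n_j))`, saturating at 0.5, through
binomial read sampling. On top of this model the package provides:

- **LiFT** — likelihood-based filtering of time series: each trajectory
  is scored under the clonal model versus a constant-proportion
  artifact model (binomial for unique variants, beta-binomial for
  recurrent ones, calibrated on synonymous variants); trajectories with
  Bayes factor ≥ 4 are called *fit*. Two timepoints suffice, so
  variants far below the classical 2%-VAF CHIP threshold become
  quantifiable.
- **Clonal structure selection** — Bayesian comparison of all
  partitions of an individual's fit variants into clones (shared latent
  size path per clone, shared stem-cell pool per individual, prior
  penalty per co-occurrence merge).
- **Fitness inference** — joint grid posterior over per-clone fitness
  and pool size via a hidden-Markov forward pass over latent clone
  sizes; MAP estimates with 90% credible intervals; gene-level medians
  and pairwise Kruskal–Wallis comparisons with ε² effect sizes.
- **Clinical forecasting** — referral times (when does growth exceed
  2 SD of the clone's own stochastic fluctuation?) and minimum
  detectable fitness for a given follow-up interval.
- **Synthetic cohorts** — a seeded generator (exact birth–death
  simulation, overdispersed artifacts, synonymous calibration sets)
  emulating a five-wave, ~3-year-spacing, ~2000× longitudinal design,
  so the whole pipeline is testable without access data.

See `docs/methods.md` for model details, priors, numerical choices and
known limitations.

## Worked example

Simulate a small cohort with three true clones (fitness 0.25, 0.15 and
0.30/yr in TET2, DNMT3A and TP53), eight flat recurrent artifacts and
eight synonymous trajectories, then run the full pipeline:

```python
from clonefit import SimScenario, CloneSpec, simulate_cohort, write_cohort
from clonefit.pipeline import PipelineConfig, run_pipeline

scenario = SimScenario(
    seed=17,
    clones=(CloneSpec(s=0.25, v0=0.04, gene="TET2"),
            CloneSpec(s=0.15, v0=0.03, gene="DNMT3A"),
            CloneSpec(s=0.30, v0=0.02, gene="TP53")),
    n_artifacts=8, n_synonymous=8,
)
cohort, truth = simulate_cohort(scenario)
write_cohort(cohort, "cohort.tsv")
report = run_pipeline(PipelineConfig(
    input_path="cohort.tsv", output_dir="out",
    use_coarse_grids=True, seed=17))
```

The report (also written to `out/report.json`) reads:

```
n_thresholded                 7      # trajectories passing the 2%-VAF baseline
n_candidates                  12     # >=2 timepoints, max VAF > 1%
n_fit                         4
growing_fraction_fit          1.00
growing_fraction_thresholded  0.71
noise.rho                     0.0089 # calibrated on the synonymous set
```

All three true clones are recovered with accurate fitness posteriors
(`out/fitness.json`):

```
chr1:1000:A:G  map_s 0.25  ci90 [0.22, 0.28]   # TET2,   true 0.25
chr1:1010:A:G  map_s 0.15  ci90 [0.11, 0.18]   # DNMT3A, true 0.15
chr1:1020:A:G  map_s 0.29  ci90 [0.26, 0.32]   # TP53,   true 0.30
chr2:5006:C:T  map_s 0.03  ci90 [0.00, 0.13]   # artifact false positive
```

One flat artifact slips past the Bayes-factor threshold but lands at
near-zero fitness — exactly the behavior the 2%-fitness floor of the
gene-level comparison is there to absorb. Every trajectory called fit
was growing, against 71% of those passing the plain VAF threshold: the
threshold keeps shrinking high-VAF clones while missing small
fast-growing ones.

The same steps are available from the shell:

```sh
clonefit simulate --scenario scenario.yaml --out-prefix sim/
clonefit run --config run.yaml          # validate -> qc -> lift -> structure -> infer -> genes
clonefit lift --input cohort.tsv --threshold 4 --out lift.tsv
clonefit forecast --v0 0.01 --fitness 0.10
# referral time: 0.59 years (7.0 months)
```

The last line is the package's headline clinical number: a clone with
10%/yr fitness first seen at 1% VAF becomes confidently measurable —
expected growth clearing two standard deviations of its own stochastic
fluctuation — after about seven months, so a follow-up draw at that
horizon can confirm or revise the fitness estimate.

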