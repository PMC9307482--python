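# Methods

## The model

Hematopoietic stem/progenitor cells (HSPCs) acquire somatic mutations; a
mutation that biases symmetric divisions toward self-renewal founds a
clone whose size `n(t)` follows a linear birth–death process with
per-cell birth rate `b = λ + s` and death (symmetric differentiation)
rate `d = λ`. The fitness `s` (per year) is the excess birth rate, so
the conditional mean grows exponentially,

    E[n(t+dt) | n(t) = n1] = n1 · e^{s·dt},

with conditional variance

    Var[n(t+dt) | n1] = n1 · ((2λ+s)/s) · e^{s·dt}(e^{s·dt} − 1),

continuous at the neutral limit (`2λ·n1·dt` at `s = 0`). The finite-time
law is approximated by a negative binomial matched to these two moments;
the approximation is validated in the test suite against an exact
event-driven (Gillespie) simulator over `s ∈ {−0.1, 0, 0.1, 0.3}`,
`dt ∈ {1, 3, 12}` years and `n1 ∈ {1, 10, 100}` at 10⁴ replicates.
When the computed variance does not exceed the mean (intervals shorter
than `1/(2λ)`), a Poisson of the same mean is used; a zero interval or
an extinct clone is a point mass.

A heterozygous clone of size `n_i` among `N_w` wild-type cells is
observed in blood at variant allele frequency (VAF)

    v_i = n_i / (2·(N_w + Σ_j n_j)),

which saturates at 0.5; read sampling at a sequenced locus is binomial
at depth DP. The deterministic (mean-field) VAF of a clone founded at
`t0` is logistic, `v(t) = 1/(2 + 2·N_w·e^{−s(t−t0)})`. The acquisition
time `t0` is fitted by maximum likelihood for display only; inference
never uses it, because conditioning on the first observed timepoint
makes all later predictions independent of `t0`. Loss of heterozygosity
is not modeled; VAFs near or above 0.5 should be treated as germline or
LOH and are excluded by the QC germline heuristic.

## Likelihood: hidden-Markov forward pass

For each `(s, N_w)` grid cell the likelihood of a clone's read-count
series is computed by filtering over a discretized latent clone size:

- **Latent grid.** Log-spaced in `n` (equivalently logit-spaced in
  `2v`), from one cell to `n(v = 0.499)`; 200 cells by default. The
  prior over cells is flat (log-uniform in clone size).
- **Transitions.** Negative-binomial CDF differences across the integer
  cell boundaries; the bottom cell absorbs extinction mass, the top cell
  is open-ended. Kernels depend only on `(N_w, dt, λ, grid)` — not on
  data — and are cached (float32), which makes replicated simulation
  studies with shared wave spacing cheap.
- **Emissions.** Binomial read likelihoods *averaged over each cell's
  VAF span* (exact via regularized incomplete-beta integrals). At
  depths around 2000× the emission is narrower than a latent cell, so
  center-point evaluation is inaccurate; cell averaging removes that
  artifact. The resulting log-likelihood surface reproduces an
  independent 2-million-particle bootstrap particle filter to ~0.02
  nats across the `N_w` range.

Priors: uniform on the fitness grid (0–1/yr, step 0.005) and
log-uniform on pool size (25 points, 10³–10⁶ cells). Both are neutral
defaults, exposed in `InferenceConfig`. A documented coarse preset
(`InferenceConfig.coarse()`: s step 0.01, 9 pool-size points, 100
latent cells) is used for replicated simulation batteries; the suite
checks that refining the latent grid moves the MAP by at most one
default fitness step.

## Shared pool and competition

All clones in an individual share `N_w`. Given `N_w`, per-clone
likelihood surfaces multiply, so the joint posterior over
`(s_1..s_C, N_w)` is tractable without a joint latent grid. Because the
VAF denominator also contains the *other* clones' sizes, a plug-in
competition round is applied when an individual carries more than one
clone: each clone's forward–backward smoothed posterior-mean size path
(per `N_w`) is added to the other clones' VAF denominators and the
likelihoods are recomputed once (`competition_rounds`, default 1; the
result is stable under further rounds). This is what lets a trajectory
whose VAF shrinks under a fitter competitor keep its own positive
inferred fitness.

Point estimates are posterior modes (MAP); intervals are the narrowest
contiguous grid interval holding ≥ 90% posterior mass, ties broken
toward the interval containing the mode.

### Interval calibration

On simulated single-clone data (s = 0.1, first-wave VAF 5%, five waves
three years apart, depth ~2000×, true pool size 10⁵), the 90% intervals
are conservative: empirical coverage is ≈ 100%, with posterior s-SD
about 1.4× the frequentist spread of the MAP across replicates. The
cause is intrinsic, not numerical: the marginal likelihood varies by
less than ~0.6 nats across three decades of `N_w`, so the posterior
hedges over pool sizes with very different drift-noise levels, and
credible intervals evaluated at a single interior truth over-cover.
Users who can justify an informative pool-size prior will obtain
tighter, less conservative intervals.

## LiFT: artifact filtering

Each candidate trajectory (≥ 2 timepoints and at least one VAF > 1%,
configurable) is scored under the clonal model (evidence = likelihood
marginalized over the fitness and pool-size grids) and under an
artifact model in which the underlying proportion θ is constant in
time. Unique variants use binomial reads; variants recurring in several
participants use beta-binomial reads with overdispersion ρ, since
recurrent artifacts are overdispersed. θ is marginalized over a Beta
prior by order-256 Gauss–Legendre quadrature (doubling the order
changes evidences by far less than the decision margins; the quadrature
is tested against a 10⁶-point brute-force integral and, for the
binomial family, against the conjugate closed form).

ρ and the θ prior are calibrated on the cohort's synonymous
trajectories: ρ by maximum likelihood of a shared beta-binomial with
per-variant proportions profiled at their pooled mean VAF, the θ prior
by moment matching to per-variant mean VAFs. Fewer than five synonymous
trajectories fall back to ρ = 0.01 and Beta(1, 99) (mean 1%).
A trajectory is called *fit* when the clonal evidence is at least 4×
the artifact evidence (Bayes factor ≥ 4, inclusive); synonymous
trajectories are never called fit. On a simulated cohort of 20 clones
(s ∈ [0.1, 0.4]) and 80 recurrent flat artifacts, sensitivity is 1.0
and the artifact false-positive rate ≈ 1–2% at the default threshold.

## Clonal structure selection

Candidate structures are all set partitions of an individual's fit
variants (Bell-number enumeration, capped at 8 variants; larger cases
must be pre-grouped). Variants in one block share a single latent size
path; each variant emits its own reads at its own observed ages.
Evidence per structure combines per-clone surfaces through the shared
`N_w` axis (without the competition plug-in, so that all candidate
structures are scored on identical terms). A prior penalty of
`log(κ)` per co-occurrence merge (κ = 0.5 by default, configurable;
κ = 0 forbids merges) encodes that multi-mutation clones are rarer.
Ties break toward more clones. Nested/subclonal relationships are
deliberately collapsed to "same clone or different clone", matching the
flat pool accounting `N(t) = N_w + Σ n_i`.

## Gene-level summaries

Per gene: variant count, median MAP fitness, and the exclusive-method
interquartile range (undefined below three variants), ranked by median.
Pairwise gene comparisons use the Kruskal–Wallis test on MAP fitness
values after excluding variants below 2%/yr (negligible advantage),
with effect size ε² = H/((n²−1)/(n+1)).

## Clinical forecast

Given a clone first seen at VAF `v0` with fitness `s`, the initial size
is `n0 = 2·N_w·v0/(1−2·v0)`; the mean and variance of `n(dt)` come from
the conditional birth–death law, mapped to the VAF scale by the delta
method. The prediction band adds binomial sampling variance at the
follow-up depth in quadrature and spans ±2 SD (configurable).

Growth counts as *confidently measurable* at the smallest `dt` (bisection
to 0.01 yr) where the expected VAF minus 2 SD of the clone's intrinsic
(birth–death) fluctuation exceeds `v0`. Sequencing noise is reported in
the band but excluded from the default detection test
(`detection_noise="process"`): the question the criterion answers is
when the clone's own growth signal exceeds its own stochastic
fluctuation. The alternative `detection_noise="combined"` additionally
requires clearing the initial measurement's 2-SD binomial band at the
configured depth, which lengthens referral times by an order of
magnitude at routine depths (years rather than months at depth 2000 for
a 1%-VAF, 10%-fitness clone) — at `v0 = 1%` the binomial SD (≈ 0.22%
VAF) dwarfs months of growth (ΔVAF ≈ 0.06% at 7 months).

Forecast defaults: pool size 10⁵ cells, follow-up depth 2000×, and
division rate λ = 1.4/yr — within the 25–50-week human HSC
inter-division estimates, and faster than the inference default of
1.0/yr. The faster rate widens the stochastic band and so lengthens
referral times, the conservative direction for scheduling follow-up.
Under these defaults a clone with 10%/yr fitness at 1% VAF becomes
confidently measurable after ≈ 7 months. The minimum detectable fitness
inverts the referral time by bisection in `s` and satisfies the
round-trip `referral_time(v0, min_detectable_fitness(v0, dt)) ≤ dt` up
to grid resolution.

## Synthetic cohorts

`simulate_cohort` emulates a longitudinal aging-cohort design: five
sampling waves three years apart from age 70 by default, targeted
sequencing depth negative-binomial around 2000× with CV 0.3, clones
specified by fitness and first-wave VAF (seeded at the first wave to
avoid wasting replicates on early extinction; flagged in the truth
table), flat recurrent artifact trajectories with beta-binomial reads
(ρ = 0.02, θ log-uniform 0.5–3% by default), and synonymous
trajectories (θ log-uniform 0.1–1%) for noise calibration. Clone paths
are drawn from the exact lineage representation of the birth–death
process (binomial survivors plus geometric offspring), which is
distributionally identical to Gillespie simulation and O(1) per
transition; the two simulators are cross-checked in the suite.

What the generator does *not* emulate: position-specific sequencing
error profiles, alignment artifacts, UMI consensus errors, depth
heterogeneity across loci, germline contamination beyond the QC band,
and loss of heterozygosity. Passing tests therefore demonstrate
correctness of the inference under the model's own assumptions plus
well-behaved overdispersed artifacts — not robustness to every failure
mode of real panels.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeds carried
  by scenarios; identical configuration and input reproduce outputs
  byte for byte (pipeline manifest records config + version + seed).
- Evidence computations are deterministic (grid quadrature, no MCMC).
- Zero-depth timepoints are dropped with a warning; an all-zero
  alt-read trajectory yields a posterior concentrated at the fitness
  grid minimum rather than an error.
- Bayes-factor and structure decisions compare log evidences directly;
  the BF ≥ threshold rule is inclusive at the boundary.
- Known limitations: fitness grid caps at 1.0/yr (faster clones pile up
  at the boundary); the competition correction is a plug-in (mean-field)
  approximation rather than a joint filter; the latent bottom cell
  aggregates extinction with size ~1, which is only adequate for clones
  observed at VAFs well above `1/(2N_w)`.
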