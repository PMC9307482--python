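"""Grid-based joint posterior over clone fitness and stem-cell pool size.

The likelihood of a clone's read-count time series under the birth-death
model is computed by a hidden-Markov forward pass over a discretized
latent clone size:

* latent grid: log-spaced in clone size ``n`` (equivalently logit-spaced
  in ``2v``), spanning one cell to a VAF just below the heterozygous
  asymptote 0.5, with a flat prior over cells;
* transition between consecutive sampling ages: the moment-matched
  negative-binomial law of :mod:`clonefit.model`, discretized by CDF
  differences over the grid-cell boundaries in count space;
* emission at each age: binomial read sampling at the cell's VAF.

Marginalizing the latent path per ``(s, N_w)`` grid cell and applying a
uniform prior on ``s`` and a log-uniform prior on ``N_w`` yields the
joint posterior; per-clone fitness marginals, MAP estimates and 90%
credible intervals follow.  Within an individual, clones are coupled by
the shared pool: given ``N_w`` the per-clone likelihoods multiply, and a
plug-in competition round feeds each clone's smoothed posterior-mean
size into the other clones' VAF denominators, so a trajectory whose VAF
shrinks under a fitter competitor is still assigned its own positive
fitness.

Transition kernels depend only on ``(N_w, dt, lambda, grid)`` — not on
the data — and are cached, which makes replicated simulation studies
with shared wave spacing cheap.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.special import logsumexp

from .io import InsufficientDataError, Trajectory

__all__ = [
    "InferenceConfig",
    "FitnessPosterior",
    "clone_loglik_grid",
    "marginal_clonal_log_evidence",
    "infer_posterior",
    "credible_interval",
    "gene_fitness_table",
    "compare_gene_fitness",
]


@dataclass
class InferenceConfig:
    """Grids and priors for the joint (s, N_w) posterior.

    Defaults: s uniform on [0, 1] per year in steps of 0.005; N_w
    log-uniform over 25 points spanning 1e3-1e6 cells; 200 latent
    clone-size cells; division rate 1/yr.
    """

    s_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 1.0 + 1e-9, 0.005), 6)
    )
    nw_grid: np.ndarray = field(default_factory=lambda: np.logspace(3, 6, 25))
    n_latent: int = 200
    lambda_div: float = 1.0
    v_max: float = 0.499
    competition_rounds: int = 1

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.nw_grid = np.asarray(self.nw_grid, dtype=float)
        for g in (self.s_grid, self.nw_grid):
            if np.any(np.diff(g) <= 0):
                raise ValueError("grids must be strictly increasing")

    @classmethod
    def coarse(cls) -> "InferenceConfig":
        """Reduced grids for replicated simulation batteries.

        s step 0.01, nine N_w points, 100 latent cells; converges to the
        default grids within one default s step on deep-coverage data
        (see the convergence test in the suite).
        """
        return cls(
            s_grid=np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 6),
            nw_grid=np.logspace(3, 6, 9),
            n_latent=100,
        )

    @property
    def log_s_prior(self) -> np.ndarray:
        return np.full(len(self.s_grid), -np.log(len(self.s_grid)))

    @property
    def log_nw_prior(self) -> np.ndarray:
        return np.full(len(self.nw_grid), -np.log(len(self.nw_grid)))

    def _grid_key(self) -> tuple:
        s = self.s_grid
        return (len(s), float(s[0]), float(s[-1]), self.n_latent,
                float(self.v_max), float(self.lambda_div))


# ---------------------------------------------------------------------------
# latent grid and cached transition kernels

_KERNEL_CACHE: OrderedDict[tuple, np.ndarray] = OrderedDict()
_KERNEL_CACHE_BYTES = 1_200_000_000


def _latent_grid(nw: float, n_latent: int, v_max: float):
    """Grid of latent clone sizes / VAFs for pool size ``nw``.

    Cells are log-spaced in clone size ``n`` from one cell up to
    ``n(v_max)``.  Returns (v, n_cells, interior, n_edges): cell-center
    VAFs and counts, the integer count edges between cells (used by the
    transition kernels), and the full real-valued count edges including
    the outer half-cells (used to integrate emissions over each cell).
    """
    y = np.linspace(np.log(1.0 / nw), np.log(2 * v_max / (1 - 2 * v_max)), n_latent)
    n_cells = nw * np.exp(y)
    v = n_cells / (2.0 * (nw + n_cells))
    mid = 0.5 * (y[:-1] + y[1:])
    interior = np.floor(nw * np.exp(mid)).astype(np.int64)
    half = 0.5 * (y[1] - y[0])
    edges_y = np.concatenate([[y[0] - half], mid, [y[-1] + half]])
    n_edges = nw * np.exp(edges_y)
    return v, n_cells, interior, n_edges


def _build_kernels(s_grid, lam, dt, n_src, interior_edges) -> np.ndarray:
    """Row-stochastic transition kernels, shape (S, K, K).

    Cell ``j -> k`` probability is the NB (or short-interval Poisson) CDF
    mass between consecutive integer edges; the bottom cell absorbs
    extinction mass (n' = 0), the top cell is open-ended.
    """
    S, K = len(s_grid), len(n_src)
    n1 = np.maximum(np.round(n_src), 1.0)
    e = np.exp(s_grid * dt)
    safe_s = np.where(s_grid == 0.0, 1.0, s_grid)
    ratio = np.where(
        s_grid == 0.0, 2.0 * lam * dt, ((2.0 * lam + s_grid) / safe_s) * (e - 1.0)
    )  # variance / mean, independent of n1
    mean = n1[None, :] * e[:, None]  # (S, K)

    cdf = np.empty((S, K, K + 1))
    cdf[..., 0] = 0.0
    cdf[..., -1] = 1.0
    kp1 = (interior_edges + 1).astype(float)[None, :]  # (1, K-1)
    nb = ratio > 1.0  # variance/mean > 1 is an s-level property
    if nb.any():
        r = mean[nb] / (ratio[nb][:, None] - 1.0)  # mean^2/(var-mean), (M, K)
        p = (1.0 / ratio[nb])[:, None, None]
        cdf[nb, :, 1:-1] = special.betainc(r[:, :, None], kp1, p)
    if (~nb).any():
        cdf[~nb, :, 1:-1] = special.pdtr(kp1 - 1.0, mean[~nb][:, :, None])
    probs = np.diff(cdf, axis=-1)
    np.clip(probs, 0.0, None, out=probs)
    probs /= probs.sum(axis=-1, keepdims=True)
    return probs


def _kernel(nw: float, dt: float, config: InferenceConfig) -> np.ndarray:
    key = (round(float(nw), 6), round(float(dt), 9), config._grid_key())
    hit = _KERNEL_CACHE.get(key)
    if hit is not None:
        _KERNEL_CACHE.move_to_end(key)
        return hit
    _, n_cells, interior, _ = _latent_grid(nw, config.n_latent, config.v_max)
    kern = _build_kernels(config.s_grid, config.lambda_div, dt, n_cells, interior)
    kern = kern.astype(np.float32)
    _KERNEL_CACHE[key] = kern
    while sum(a.nbytes for a in _KERNEL_CACHE.values()) > _KERNEL_CACHE_BYTES:
        _KERNEL_CACHE.popitem(last=False)
    return kern


# ---------------------------------------------------------------------------
# clone observations

def merge_clone_obs(trajectories: list[Trajectory]) -> tuple[np.ndarray, list[list[tuple[int, int]]]]:
    """Union of member-variant observations of one clone.

    Returns (ages, reads) with ``reads[k]`` the list of (alt, depth)
    pairs emitted at age ``ages[k]``; each member variant contributes at
    its own observed ages.
    """
    ages = sorted({float(a) for t in trajectories for a in t.ages})
    reads: list[list[tuple[int, int]]] = [[] for _ in ages]
    index = {a: i for i, a in enumerate(ages)}
    for t in trajectories:
        for p in t.points:
            if p.depth > 0:
                reads[index[float(p.age)]].append((p.alt_reads, p.depth))
    return np.asarray(ages), reads


def _log_emissions(reads, nw, n_cells, n_edges, offsets=None) -> np.ndarray:
    """(n_ages, K) cell-averaged binomial log-emission matrix.

    Each cell's emission is the binomial likelihood averaged over the
    cell's VAF span (exact via regularized incomplete-beta integrals),
    which keeps the forward pass accurate even when read depth makes the
    emission narrower than a latent cell.  ``offsets[k]`` (cells) is the
    combined size of the other clones in the pool at age k; it enlarges
    the VAF denominator.
    """
    n_ages, K = len(reads), len(n_cells)
    out = np.zeros((n_ages, K))
    tiny = np.log(np.finfo(float).tiny)
    for k in range(n_ages):
        extra = offsets[k] if offsets is not None and offsets[k] > 0 else 0.0
        v_edges = n_edges / (2.0 * (nw + n_edges + extra))
        dv = np.diff(v_edges)
        for alt, depth in reads[k]:
            # int_lo^hi C(d,a) v^a (1-v)^(d-a) dv = I(a+1, d-a+1)(hi..lo)/(d+1)
            cdf = special.betainc(alt + 1.0, depth - alt + 1.0, v_edges)
            mass = np.maximum(np.diff(cdf), 0.0) / (depth + 1.0)
            with np.errstate(divide="ignore"):
                out[k] += np.maximum(np.log(mass / dv), tiny)
    return out


def _forward(ages, reads, config, nw, offsets=None, keep_beliefs=False):
    """Scaled forward pass for all s at one pool size.

    Returns (loglik (S,), beliefs) where beliefs is the list of filtered
    (S, K) distributions per age when requested.
    """
    _, n_cells, _, n_edges = _latent_grid(nw, config.n_latent, config.v_max)
    logem = _log_emissions(reads, nw, n_cells, n_edges, offsets)
    S, K = len(config.s_grid), config.n_latent
    shift = logem.max(axis=1)
    em = np.exp(logem - shift[:, None])

    belief = np.broadcast_to(em[0] / K, (S, K)).copy()
    loglik = np.full(S, shift[0])
    c = belief.sum(axis=1)
    ok = c > 0
    loglik[~ok] = -np.inf
    belief[ok] /= c[ok, None]
    loglik[ok] += np.log(c[ok])
    beliefs = [belief.copy()] if keep_beliefs else None

    for g, dt in enumerate(np.diff(ages)):
        T = _kernel(nw, float(dt), config)
        belief = np.einsum("sk,skj->sj", belief, T, optimize=True)
        belief *= em[g + 1]
        c = belief.sum(axis=1)
        ok = c > 0
        loglik[~ok] = -np.inf
        belief[ok] /= c[ok, None]
        loglik[ok] += np.log(c[ok]) + shift[g + 1]
        if keep_beliefs:
            beliefs.append(belief.copy())
    return loglik, beliefs


def clone_loglik_grid(ages, reads, config: InferenceConfig, offsets=None) -> np.ndarray:
    """Log-likelihood surface over the (s, N_w) grids for one clone.

    ``offsets``: optional (NW, n_ages) array of competitor pool sizes.
    """
    if len(ages) < 2:
        raise InsufficientDataError("clone likelihood needs >= 2 observation ages")
    S, NW = len(config.s_grid), len(config.nw_grid)
    L = np.empty((S, NW))
    for j, nw in enumerate(config.nw_grid):
        off = offsets[j] if offsets is not None else None
        L[:, j], _ = _forward(ages, reads, config, nw, off)
    return L


def _smoothed_sizes(ages, reads, config, L, offsets=None) -> np.ndarray:
    """Posterior-mean clone size per (N_w, age), marginal over s and the path."""
    S, NW = len(config.s_grid), len(config.nw_grid)
    out = np.zeros((NW, len(ages)))
    for j, nw in enumerate(config.nw_grid):
        _, n_cells, _, n_edges = _latent_grid(nw, config.n_latent, config.v_max)
        off = offsets[j] if offsets is not None else None
        _, beliefs = _forward(ages, reads, config, nw, off, keep_beliefs=True)
        # backward smoothing with the same kernels
        logem = _log_emissions(reads, nw, n_cells, n_edges, off)
        em = np.exp(logem - logem.max(axis=1)[:, None])
        n_ages = len(ages)
        gammas = [None] * n_ages
        back = np.ones((S, config.n_latent))
        gammas[-1] = beliefs[-1]
        for g in range(n_ages - 2, -1, -1):
            dt = float(ages[g + 1] - ages[g])
            T = _kernel(nw, dt, config)
            back = np.einsum("skj,sj->sk", T, em[g + 1] * back, optimize=True)
            m = back.max(axis=1, keepdims=True)
            back = np.where(m > 0, back / np.where(m > 0, m, 1.0), 0.0)
            gam = beliefs[g] * back
            z = gam.sum(axis=1, keepdims=True)
            gammas[g] = np.where(z > 0, gam / np.where(z > 0, z, 1.0), beliefs[g])
        # collapse over s with the posterior weight at this nw
        w = config.log_s_prior + L[:, j]
        w = np.exp(w - w.max())
        w /= w.sum()
        for k in range(n_ages):
            out[j, k] = float(w @ (gammas[k] @ n_cells))
    return out


def marginal_clonal_log_evidence(ages, reads, config: InferenceConfig) -> float:
    """Evidence of the single-clone model: likelihood marginalized over the
    s and N_w prior grids."""
    L = clone_loglik_grid(ages, reads, config)
    return float(logsumexp(L + config.log_s_prior[:, None] + config.log_nw_prior[None, :]))


# ---------------------------------------------------------------------------
# posteriors

@dataclass
class FitnessPosterior:
    """Discretized fitness posterior for one clone (plus the shared N_w)."""

    variant_ids: frozenset
    s_grid: np.ndarray
    s_density: np.ndarray
    map_s: float
    ci90: tuple[float, float]
    nw_grid: np.ndarray
    nw_density: np.ndarray
    map_nw: float

    def to_dict(self) -> dict:
        return {
            "variant_ids": sorted(self.variant_ids),
            "s_grid": self.s_grid.tolist(),
            "s_density": self.s_density.tolist(),
            "map_s": self.map_s,
            "ci90": list(self.ci90),
            "nw_grid": self.nw_grid.tolist(),
            "nw_density": self.nw_density.tolist(),
            "map_nw": self.map_nw,
        }


def credible_interval(grid, density, mass: float = 0.90) -> tuple[float, float]:
    """Narrowest contiguous grid interval holding at least ``mass``.

    Ties are broken toward the interval containing the mode, then toward
    the left.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    grid = np.asarray(grid, dtype=float)
    density = np.asarray(density, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(density)])
    K = len(grid)
    mode = int(np.argmax(density))
    best = None  # (width, not_contains_mode, lo_index, hi_index)
    j = 0
    for i in range(K):
        j = max(j, i)
        while j < K and csum[j + 1] - csum[i] < mass - 1e-9:
            j += 1
        if j >= K:
            break
        width = grid[j] - grid[i]
        contains = i <= mode <= j
        cand = (width + 1e-15, not contains, i, j)
        if best is None or (cand[0] < best[0] - 1e-12) or (
            abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]
        ):
            best = cand
    if best is None:  # density mass below target (degenerate); whole grid
        return float(grid[0]), float(grid[-1])
    return float(grid[best[2]]), float(grid[best[3]])


def _posterior_from_L(L_list, config):
    """Combine per-clone likelihood surfaces through the shared N_w axis."""
    log_s, log_nw = config.log_s_prior, config.log_nw_prior
    logM = [logsumexp(L + log_s[:, None], axis=0) for L in L_list]  # (NW,) each
    log_pnw = log_nw + np.sum(logM, axis=0)
    log_pnw -= logsumexp(log_pnw)
    pnw = np.exp(log_pnw)

    out = []
    for c, L in enumerate(L_list):
        other = log_nw + np.sum([logM[k] for k in range(len(L_list)) if k != c], axis=0) \
            if len(L_list) > 1 else log_nw
        joint = log_s[:, None] + L + other[None, :]
        log_ps = logsumexp(joint, axis=1)
        log_ps -= logsumexp(log_ps)
        ps = np.exp(log_ps)
        map_s = float(config.s_grid[int(np.argmax(ps))])
        ci = credible_interval(config.s_grid, ps, 0.90)
        out.append((ps, map_s, ci))
    map_nw = float(config.nw_grid[int(np.argmax(pnw))])
    return out, pnw, map_nw


def infer_posterior(
    trajectories: list[Trajectory], partition, config: InferenceConfig | None = None
) -> list[FitnessPosterior]:
    """Joint fitness / pool-size posterior for one individual.

    ``partition``: iterable of variant-id sets (one per clone), or an
    object with a ``partition`` attribute.  Every clone needs at least
    two observation ages.  With more than one clone, a plug-in
    competition round feeds each clone's smoothed size trajectory into
    the others' VAF denominators.
    """
    config = config or InferenceConfig()
    clones = [frozenset(c) for c in getattr(partition, "partition", partition)]
    by_vid = {t.variant_id: t for t in trajectories}
    clone_trajs = [[by_vid[v] for v in sorted(c)] for c in clones]
    obs = [merge_clone_obs(ts) for ts in clone_trajs]
    for ages, _ in obs:
        if len(ages) < 2:
            raise InsufficientDataError("each clone needs >= 2 observation ages")

    L_list = [clone_loglik_grid(a, r, config) for a, r in obs]
    if len(clones) > 1 and config.competition_rounds > 0:
        for _ in range(config.competition_rounds):
            sizes = [
                _smoothed_sizes(a, r, config, L) for (a, r), L in zip(obs, L_list)
            ]  # each (NW, n_ages_c)
            offsets = []
            for c, (ages_c, _) in enumerate(obs):
                off = np.zeros((len(config.nw_grid), len(ages_c)))
                for k, (ages_k, _) in enumerate(obs):
                    if k == c:
                        continue
                    for j in range(len(config.nw_grid)):
                        off[j] += np.exp(
                            np.interp(ages_c, ages_k, np.log(sizes[k][j] + 1.0))
                        ) - 1.0
                offsets.append(off)
            L_list = [
                clone_loglik_grid(a, r, config, off)
                for (a, r), off in zip(obs, offsets)
            ]

    per_clone, pnw, map_nw = _posterior_from_L(L_list, config)
    return [
        FitnessPosterior(
            variant_ids=clones[c],
            s_grid=config.s_grid.copy(),
            s_density=ps,
            map_s=map_s,
            ci90=ci,
            nw_grid=config.nw_grid.copy(),
            nw_density=pnw.copy(),
            map_nw=map_nw,
        )
        for c, (ps, map_s, ci) in enumerate(per_clone)
    ]


# ---------------------------------------------------------------------------
# gene-level aggregation

def gene_fitness_table(posteriors: list[FitnessPosterior], gene_of: dict) -> pd.DataFrame:
    """Per-gene summary of MAP fitness estimates.

    One row per gene: variant count, median MAP, exclusive-method
    interquartile range (NaN below three variants), ranked by median MAP
    descending.  ``gene_of`` maps variant_id -> gene symbol.
    """
    rows = [
        {"variant_id": vid, "gene": gene_of[vid], "map_s": p.map_s}
        for p in posteriors for vid in sorted(p.variant_ids)
    ]
    per_variant = pd.DataFrame(rows, columns=["variant_id", "gene", "map_s"])
    recs = []
    for gene, grp in per_variant.groupby("gene"):
        x = grp["map_s"].to_numpy()
        if len(x) >= 3:
            q1, q3 = np.percentile(x, [25, 75], method="weibull")
        else:
            q1 = q3 = np.nan
        recs.append({
            "gene": gene, "n_variants": len(x), "median_map_s": float(np.median(x)),
            "iqr_low": q1, "iqr_high": q3,
        })
    table = pd.DataFrame(recs).sort_values(
        ["median_map_s", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    table.attrs["per_variant"] = per_variant
    return table


def compare_gene_fitness(per_variant: pd.DataFrame, min_fitness: float = 0.02):
    """Pairwise Kruskal-Wallis comparison of gene fitness distributions.

    Variants with MAP fitness below ``min_fitness`` are excluded; genes
    with fewer than two retained variants are reported as untestable.
    Effect size is epsilon-squared, ``H / ((n^2 - 1)/(n + 1))``.
    Returns (pairs DataFrame, list of untestable genes).
    """
    kept = per_variant[per_variant["map_s"] >= min_fitness]
    groups = {g: grp["map_s"].to_numpy() for g, grp in kept.groupby("gene")}
    testable = sorted(g for g, x in groups.items() if len(x) >= 2)
    untestable = sorted(set(per_variant["gene"]) - set(testable))
    rows = []
    for i, ga in enumerate(testable):
        for gb in testable[i + 1:]:
            xa, xb = groups[ga], groups[gb]
            n = len(xa) + len(xb)
            if np.all(np.concatenate([xa, xb]) == xa[0]):
                h, p = 0.0, 1.0
            else:
                h, p = stats.kruskal(xa, xb)
            eps2 = h / ((n**2 - 1) / (n + 1))
            rows.append({
                "gene_a": ga, "gene_b": gb, "n": n, "H": float(h),
                "p_value": float(p), "epsilon_sq": float(eps2),
                "significant": bool(p < 0.05),
            })
    cols = ["gene_a", "gene_b", "n", "H", "p_value", "epsilon_sq", "significant"]
    return pd.DataFrame(rows, columns=cols), untestable
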