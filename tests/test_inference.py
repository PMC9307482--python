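"""Posterior machinery: credible intervals, grid convergence, gene tables."""

import numpy as np
import pytest
from scipy import stats

from clonefit.inference import (FitnessPosterior, InferenceConfig,
                                compare_gene_fitness, credible_interval,
                                gene_fitness_table, infer_posterior)
from clonefit.model import deterministic_vaf
from clonefit.simulate import CloneSpec, SimScenario, simulate_cohort
from conftest import make_trajectory


def _noiseless_logistic_traj(s=0.15, nw=1e5, t0=40.0, depth=2000,
                             ages=(70.0, 73.0, 76.0, 79.0, 82.0)):
    ages = np.asarray(ages)
    v = deterministic_vaf(ages, s, nw, t0)
    return make_trajectory(v, ages=ages, depth=depth)


class TestCredibleInterval:
    def test_point_mass(self):
        grid = np.linspace(0, 1, 11)
        dens = np.zeros(11)
        dens[4] = 1.0
        assert credible_interval(grid, dens) == (grid[4], grid[4])

    def test_uniform_tie_breaks_toward_mode_window(self):
        grid = np.arange(10.0)
        dens = np.full(10, 0.1)
        assert credible_interval(grid, dens, 0.9) == (0.0, 8.0)

    def test_symmetric_density_gives_symmetric_interval(self):
        grid = np.linspace(-5, 5, 201)
        dens = stats.norm.pdf(grid)
        dens /= dens.sum()
        lo, hi = credible_interval(grid, dens, 0.9)
        # narrowest >= 0.9 window on a discrete Gaussian can sit a few cells
        # off center; both endpoints must straddle the 5% tails
        step = grid[1] - grid[0]
        assert lo == pytest.approx(-1.645, abs=4 * step)
        assert hi == pytest.approx(1.645, abs=4 * step)
        assert dens[(grid >= lo) & (grid <= hi)].sum() >= 0.9

    def test_mass_bounds_validated(self):
        with pytest.raises(ValueError):
            credible_interval(np.arange(3.0), np.full(3, 1 / 3), mass=1.5)


class TestInferPosterior:
    def test_noiseless_logistic_recovers_fitness(self, coarse_config):
        traj = _noiseless_logistic_traj(s=0.15)
        post = infer_posterior([traj], [{traj.variant_id}], coarse_config)[0]
        step = coarse_config.s_grid[1] - coarse_config.s_grid[0]
        assert abs(post.map_s - 0.15) <= step + 1e-12
        assert post.ci90[0] <= post.map_s <= post.ci90[1]
        assert post.s_density.sum() == pytest.approx(1.0)
        assert post.nw_density.sum() == pytest.approx(1.0)

    def test_all_zero_alt_counts_give_low_fitness_posterior(self, coarse_config):
        traj = make_trajectory([0.0, 0.0, 0.0])
        post = infer_posterior([traj], [{traj.variant_id}], coarse_config)[0]
        assert post.map_s <= 0.02

    def test_trajectory_order_is_irrelevant(self, coarse_config):
        sc = SimScenario(seed=40, clones=(
            CloneSpec(s=0.1, v0=0.03, participant="P0"),
            CloneSpec(s=0.3, v0=0.02, participant="P0"),
        ))
        cohort, _ = simulate_cohort(sc)
        trajs = cohort.trajectories
        part = [{trajs[0].variant_id}, {trajs[1].variant_id}]
        a = infer_posterior(trajs, part, coarse_config)
        b = infer_posterior(trajs[::-1], part, coarse_config)
        for pa in a:
            pb = next(p for p in b if p.variant_ids == pa.variant_ids)
            np.testing.assert_allclose(pa.s_density, pb.s_density, rtol=1e-9)

    def test_latent_grid_refinement_converges(self):
        base = InferenceConfig.coarse()
        fine = InferenceConfig.coarse()
        fine.n_latent = 2 * base.n_latent
        traj = _noiseless_logistic_traj(s=0.12)
        step = base.s_grid[1] - base.s_grid[0]
        maps = [
            infer_posterior([traj], [{traj.variant_id}], cfg)[0].map_s
            for cfg in (base, fine)
        ]
        assert abs(maps[0] - maps[1]) <= step + 1e-12

    def test_competing_clone_explains_shrinking_vaf(self, coarse_config):
        # clone A (s=0.1) is overtaken by B (s=0.3); A's VAF shrinks but its
        # inferred fitness must stay clearly positive.
        sc = SimScenario(seed=3, clones=(
            CloneSpec(s=0.1, v0=0.08, participant="P0"),
            CloneSpec(s=0.3, v0=0.05, participant="P0"),
        ), waves=(70, 73, 76, 79, 82, 85, 88))
        cohort, _ = simulate_cohort(sc)
        a, b = cohort.trajectories
        assert a.vafs[-1] < a.vafs[0]  # A is shrinking in VAF terms
        posts = infer_posterior([a, b], [{a.variant_id}, {b.variant_id}],
                                coarse_config)
        map_a = next(p for p in posts if a.variant_id in p.variant_ids).map_s
        map_b = next(p for p in posts if b.variant_id in p.variant_ids).map_s
        assert abs(map_a - 0.1) <= 0.07 and map_a > 0.02
        assert abs(map_b - 0.3) <= 0.08


def _posterior_stub(vids, map_s):
    grid = np.linspace(0, 1, 11)
    dens = np.zeros(11)
    dens[int(round(map_s * 10))] = 1.0
    return FitnessPosterior(
        variant_ids=frozenset(vids), s_grid=grid, s_density=dens, map_s=map_s,
        ci90=(map_s, map_s), nw_grid=np.array([1e5]), nw_density=np.array([1.0]),
        map_nw=1e5,
    )


class TestGeneTable:
    def test_medians_and_ranking(self):
        posts = [_posterior_stub([f"v{i}"], m) for i, m in
                 enumerate([0.1, 0.2, 0.3, 0.5])]
        gene_of = {"v0": "TET2", "v1": "TET2", "v2": "TET2", "v3": "TP53"}
        table = gene_fitness_table(posts, gene_of)
        assert list(table["gene"]) == ["TP53", "TET2"]  # ranked by median desc
        tet2 = table[table["gene"] == "TET2"].iloc[0]
        assert tet2["median_map_s"] == pytest.approx(0.2)
        assert tet2["n_variants"] == 3

    def test_single_variant_gene_has_no_iqr(self):
        table = gene_fitness_table([_posterior_stub(["v0"], 0.1)], {"v0": "JAK2"})
        row = table.iloc[0]
        assert row["median_map_s"] == pytest.approx(0.1)
        assert np.isnan(row["iqr_low"]) and np.isnan(row["iqr_high"])

    def test_every_gene_appears_exactly_once(self):
        posts = [_posterior_stub([f"v{i}"], 0.1 * (1 + i % 3)) for i in range(9)]
        gene_of = {f"v{i}": f"G{i % 4}" for i in range(9)}
        table = gene_fitness_table(posts, gene_of)
        assert sorted(table["gene"]) == ["G0", "G1", "G2", "G3"]


class TestCompareGeneFitness:
    def _frame(self, groups):
        import pandas as pd
        rows = [{"variant_id": f"{g}{i}", "gene": g, "map_s": v}
                for g, vals in groups.items() for i, v in enumerate(vals)]
        return pd.DataFrame(rows)

    def test_identical_groups_have_zero_h(self):
        pairs, _ = compare_gene_fitness(
            self._frame({"A": [0.1, 0.2], "B": [0.1, 0.2]}), min_fitness=0.0)
        assert pairs.iloc[0]["H"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_ranked_toy_example(self):
        # ranks 1..6, rank sums 6 and 15: H = 12/(6*7) * (36/3 + 225/3) - 21
        pairs, _ = compare_gene_fitness(
            self._frame({"A": [0.1, 0.2, 0.3], "B": [0.4, 0.5, 0.6]}),
            min_fitness=0.0)
        h_oracle = 12 / (6 * 7) * (36 / 3 + 225 / 3) - 3 * 7
        row = pairs.iloc[0]
        assert row["H"] == pytest.approx(h_oracle, abs=1e-9)
        assert row["H"] == pytest.approx(3.857, abs=0.001)
        assert row["epsilon_sq"] == pytest.approx(h_oracle / (6 - 1))

    def test_rank_invariance_under_shift(self):
        a = self._frame({"A": [0.11, 0.22, 0.31], "B": [0.4, 0.52, 0.6]})
        b = a.copy()
        b["map_s"] = b["map_s"] + 0.1
        ha, _ = compare_gene_fitness(a, min_fitness=0.0)
        hb, _ = compare_gene_fitness(b, min_fitness=0.0)
        assert ha.iloc[0]["H"] == pytest.approx(hb.iloc[0]["H"])

    def test_low_fitness_variants_excluded_and_small_genes_untestable(self):
        frame = self._frame({
            "A": [0.1, 0.2, 0.015], "B": [0.3, 0.4], "C": [0.25, 0.01]})
        pairs, untestable = compare_gene_fitness(frame, min_fitness=0.02)
        assert untestable == ["C"]
        assert set(zip(pairs["gene_a"], pairs["gene_b"])) == {("A", "B")}
        assert pairs.iloc[0]["n"] == 4  # the 0.015 variant was dropped
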