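"""Noise calibration, artifact/clonal evidences and LiFT classification."""

import warnings

import numpy as np
import pytest
from scipy import stats
from scipy.special import betaln, gammaln

from clonefit.inference import InferenceConfig
from clonefit.io import Cohort, InsufficientDataError, TimepointObs
from clonefit.lift import (ArtifactNoiseParams, CandidateRule, artifact_evidence,
                           calibrate_noise, clonal_evidence, is_fit, lift_classify)
from clonefit.simulate import CloneSpec, SimScenario, simulate_cohort
from conftest import make_trajectory


def _synonymous_set(rng, n=200, rho=0.0, theta=0.005, depth=2000, waves=3):
    trajs = []
    for i in range(n):
        if rho > 0:
            conc = (1 - rho) / rho
            ps = rng.beta(theta * conc, (1 - theta) * conc, size=waves)
        else:
            ps = np.full(waves, theta)
        alts = rng.binomial(depth, ps)
        t = make_trajectory(np.zeros(waves), depth=depth, variant=f"v{i}",
                            participant=f"P{i}", consequence="synonymous")
        t.points = [
            TimepointObs(age=70.0 + 3 * k, depth=depth, alt_reads=int(a))
            for k, a in enumerate(alts)
        ]
        trajs.append(t)
    return trajs


class TestCalibrateNoise:
    def test_binomial_reads_give_near_zero_overdispersion(self, rng):
        noise = calibrate_noise(_synonymous_set(rng, n=200, rho=0.0))
        assert noise.rho <= 0.003

    def test_overdispersion_recovered_within_half(self, rng):
        noise = calibrate_noise(_synonymous_set(rng, n=200, rho=0.05))
        assert 0.025 <= noise.rho <= 0.075

    def test_theta_prior_tracks_synonymous_level(self, rng):
        noise = calibrate_noise(_synonymous_set(rng, n=100, theta=0.008))
        mean = noise.theta_a / (noise.theta_a + noise.theta_b)
        assert mean == pytest.approx(0.008, rel=0.3)

    def test_too_few_trajectories_fall_back_to_defaults(self):
        with pytest.warns(UserWarning, match="default"):
            noise = calibrate_noise([])
        assert noise == ArtifactNoiseParams(rho=0.01, theta_a=1.0, theta_b=99.0)


class TestArtifactEvidence:
    def setup_method(self):
        self.traj = make_trajectory([0.0], depth=10)
        self.traj.points = [TimepointObs(70, 10, 2), TimepointObs(73, 12, 3),
                            TimepointObs(76, 8, 1)]
        self.noise = ArtifactNoiseParams(rho=0.05, theta_a=2.0, theta_b=30.0)

    def test_binomial_family_matches_conjugate_closed_form(self):
        alts, depths = np.array([2, 3, 1]), np.array([10, 12, 8])
        log_c = float(np.sum(gammaln(depths + 1) - gammaln(alts + 1)
                             - gammaln(depths - alts + 1)))
        closed = log_c + betaln(2.0 + alts.sum(), 30.0 + (depths - alts).sum()) \
            - betaln(2.0, 30.0)
        assert artifact_evidence(self.traj, self.noise, "binomial") == \
            pytest.approx(closed, abs=1e-10)

    def test_overdispersion_limit_reduces_to_binomial(self):
        tiny = ArtifactNoiseParams(rho=1e-8, theta_a=2.0, theta_b=30.0)
        diff = artifact_evidence(self.traj, tiny, "beta_binomial") \
            - artifact_evidence(self.traj, tiny, "binomial")
        assert abs(diff) < 1e-4

    def test_identical_counts_identical_evidence(self):
        other = make_trajectory([0.0], variant="other", participant="Q")
        other.points = list(self.traj.points)
        assert artifact_evidence(other, self.noise, "beta_binomial") == \
            artifact_evidence(self.traj, self.noise, "beta_binomial")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            artifact_evidence(self.traj, self.noise, "gaussian")


class TestClonalEvidence:
    def test_variant_relabeling_is_irrelevant(self, coarse_config):
        a = make_trajectory([0.02, 0.05, 0.09], variant="chr1:5:A:T")
        b = make_trajectory([0.02, 0.05, 0.09], variant="chrX:99:G:C")
        assert clonal_evidence(a, coarse_config) == clonal_evidence(b, coarse_config)

    def test_single_timepoint_rejected(self, coarse_config):
        with pytest.raises(InsufficientDataError):
            clonal_evidence(make_trajectory([0.05]), coarse_config)

    def test_growth_beats_artifact_and_flat_does_not(self, coarse_config):
        noise = ArtifactNoiseParams()
        growing = make_trajectory([0.02, 0.045, 0.10, 0.19])
        flat = make_trajectory([0.011, 0.009, 0.0105, 0.010])
        for traj, expect_fit in ((growing, True), (flat, False)):
            bf = clonal_evidence(traj, coarse_config) \
                - artifact_evidence(traj, noise, "binomial")
            assert bool(bf >= np.log(4)) == expect_fit


class TestLiftClassify:
    def test_boundary_bayes_factor_is_fit(self):
        assert is_fit(np.log(4.0), 0.0, threshold=4.0)
        assert not is_fit(np.log(3.99), 0.0, threshold=4.0)

    def test_candidate_rule_excludes_low_vaf_and_short_series(self, coarse_config):
        low = make_trajectory([0.004, 0.005], variant="low")
        short = make_trajectory([0.30], variant="short", participant="P2")
        ok = make_trajectory([0.02, 0.05, 0.1], variant="ok", participant="P3")
        res = lift_classify(Cohort([low, short, ok]), noise=ArtifactNoiseParams(),
                            config=coarse_config)
        assert [r.trajectory.variant_id for r in res] == ["ok"]

    def test_synonymous_never_fit(self, coarse_config):
        syn = make_trajectory([0.02, 0.05, 0.11], consequence="synonymous")
        res = lift_classify(Cohort([syn]), noise=ArtifactNoiseParams(),
                            config=coarse_config)
        assert res[0].call == "filtered"
        # same counts as a missense variant would be called fit
        mis = make_trajectory([0.02, 0.05, 0.11])
        res2 = lift_classify(Cohort([mis]), noise=ArtifactNoiseParams(),
                             config=coarse_config)
        assert res2[0].call == "fit"

    def test_raising_threshold_shrinks_fit_set(self, coarse_config):
        sc = SimScenario(seed=21, clones=tuple(
            CloneSpec(s=s, v0=0.02) for s in (0.05, 0.1, 0.2, 0.3)),
            n_artifacts=10, n_synonymous=10)
        cohort, _ = simulate_cohort(sc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            noise = calibrate_noise(cohort.synonymous())
        fit_sets = []
        for th in (2.0, 4.0, 16.0):
            res = lift_classify(cohort, th, noise=noise, config=coarse_config)
            fit_sets.append({
                (r.trajectory.participant_id, r.trajectory.variant_id)
                for r in res if r.call == "fit"
            })
        assert fit_sets[2] <= fit_sets[1] <= fit_sets[0]

    def test_recurrent_variants_use_beta_binomial_family(self, coarse_config):
        a = make_trajectory([0.02, 0.05], variant="shared", participant="P1")
        b = make_trajectory([0.02, 0.04], variant="shared", participant="P2")
        c = make_trajectory([0.02, 0.05], variant="solo", participant="P3")
        cohort = Cohort([a, b, c])
        res = lift_classify(cohort, noise=ArtifactNoiseParams(), config=coarse_config)
        fam = {r.trajectory.variant_id: r.artifact_family for r in res}
        assert fam["shared"] == "beta_binomial" and fam["solo"] == "binomial"
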