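import numpy as np
import pytest

from conftest import (
    enumerate_tiny_posterior,
    tiny_instance,
    tiny_mcmc_distribution,
    total_variation,
)
from openscr.infer import (
    FitConfig,
    OpenSCRCormackJollySeber,
    OpenSCRJollySeber,
    fit_cjs,
    fit_open_scr,
    gelman_rubin,
    summarize_posterior,
    unequal_intervals,
)
from openscr.model import EncounterData, StateSpace, TrapArray
from openscr.simulate import make_grid, make_state_space


class TestGelmanRubin:
    def test_identical_chains_give_one(self):
        x = np.random.default_rng(0).normal(size=(1, 2000))
        chains = np.vstack([x, x])
        assert gelman_rubin({"p": chains})["p"] == pytest.approx(1.0, abs=1e-3)

    def test_same_distribution_converged(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(3, 10_000))
        assert gelman_rubin({"p": chains})["p"] < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 2000)) + np.array([[0.0], [10.0]])
        assert gelman_rubin({"p": chains})["p"] > 5.0

    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            gelman_rubin({"p": np.zeros((1, 100))})


class TestSummaries:
    def test_constant_chain(self):
        s = summarize_posterior({"c": np.full((2, 50), 3.25)})
        row = s.loc["c"]
        assert row["mean"] == 3.25 and row["sd"] == 0.0
        assert row["q2.5"] == 3.25 and row["q97.5"] == 3.25

    def test_normal_quantiles(self):
        draws = np.random.default_rng(3).normal(size=(1, 1_000_000))
        row = summarize_posterior({"x": draws}).loc["x"]
        assert row["q2.5"] == pytest.approx(-1.9600, abs=0.01)
        assert row["q97.5"] == pytest.approx(1.9600, abs=0.01)

    def test_density_is_abundance_over_area(self, short_fit):
        area = short_fit.state_space.area
        assert np.allclose(short_fit.D, short_fit.N / area)
        s = summarize_posterior(short_fit)
        assert s.loc["D[1]", "mean"] == pytest.approx(
            s.loc["N[1]", "mean"] / area)


class TestContinuousPosterior:
    def test_center_and_detection_updates_match_quadrature(self):
        """With the alive state pinned by the data (one individual detected
        in the single period), the 4-D posterior over (center, lambda0,
        sigma_p) is computable by direct numeric integration; the sampler
        must reproduce its marginal means.

        This exercises exactly the moves the trajectory-enumeration oracle
        cannot see: activity-center MH and the detection-parameter updates.
        """
        K = 20
        y = np.zeros((1, 2, 1), dtype=int)
        y[0, 0, 0] = 3
        y[0, 1, 0] = 1
        traps = TrapArray(trap_id=[1, 2], x=[-0.5, 0.5], y=[0.0, 0.0],
                          effort=np.full((2, 1), K))
        S = StateSpace(-3, 3, -3, 3)

        gx = np.linspace(-3, 3, 41)
        SX, SY = np.meshgrid(gx, gx, indexing="ij")
        d2 = [(SX + 0.5) ** 2 + SY ** 2, (SX - 0.5) ** 2 + SY ** 2]
        lam = np.linspace(0.05, 10, 100)
        sig = np.linspace(0.05, 6, 100)
        W = np.zeros((len(lam), len(sig)))
        for a, l0 in enumerate(lam):
            for b, s0 in enumerate(sig):
                L = np.ones_like(SX)
                for j, yv in enumerate((3, 1)):
                    p = -np.expm1(-l0 * np.exp(-d2[j] / (2 * s0 * s0)))
                    p = np.clip(p, 1e-300, 1 - 1e-15)
                    L *= p ** yv * (1 - p) ** (K - yv)
                W[a, b] = L.sum()
        W /= W.sum()
        exact_lam = (W.sum(1) * lam).sum()
        exact_sig = (W.sum(0) * sig).sum()

        config = FitConfig(movement_model="constant", M=1, state_space=S,
                           n_chains=2, n_iter=120_000, n_burnin=10_000,
                           thin=5, seed=11, sigma_p_max=6.0)
        post = fit_open_scr(EncounterData(y=y, M=1), traps, config)
        assert post.lambda0.mean() == pytest.approx(exact_lam, abs=0.08)
        assert post.sigma_p.mean() == pytest.approx(exact_sig, abs=0.08)


class TestTrajectoryPosterior:
    def test_mcmc_matches_enumeration(self):
        """Joint z posterior from MCMC agrees with brute-force enumeration."""
        exact = enumerate_tiny_posterior()
        approx = tiny_mcmc_distribution(n_draws=40_000, seed=17)
        assert total_variation(exact, approx) < 0.03

    def test_no_revival_in_sampled_trajectories(self, short_fit):
        z = short_fit.z.reshape(-1, *short_fit.z.shape[2:])
        for draw in z[::37]:
            on = np.diff(draw.astype(int), axis=1)
            # a 0->1 flip after a 1->0 flip would need diff pattern -1 then +1
            for row, d in zip(draw, on):
                starts = np.flatnonzero(d == 1)
                stops = np.flatnonzero(d == -1)
                assert len(starts) + (row[0] == 1) <= 1
                assert len(stops) <= 1

    def test_abundance_bounded_by_M(self, short_fit):
        assert short_fit.N.max() <= 150
        assert (short_fit.phi > 0).all() and (short_fit.phi < 1).all()
        assert ((short_fit.gamma > 0) & (short_fit.gamma < 1)).all()


class TestFitBehaviour:
    def test_exchangeability_under_relabelling(self, default_dataset):
        sim = default_dataset
        S = make_state_space(sim.traps, 2.0)
        config = FitConfig(movement_model="constant", M=150, state_space=S,
                           n_chains=1, n_iter=800, n_burnin=200, seed=9)
        post1 = fit_open_scr(sim.data, sim.traps, config)
        perm = np.random.default_rng(5).permutation(sim.data.n_observed)
        shuffled = EncounterData(y=sim.data.y[perm], M=sim.data.M)
        post2 = fit_open_scr(shuffled, sim.traps, config)
        assert np.array_equal(post1.phi, post2.phi)
        assert np.array_equal(post1.N, post2.N)
        assert np.array_equal(post1.lambda0, post2.lambda0)

    def test_no_detections_leaves_phi_at_prior(self):
        # flat likelihood in phi: posterior should look Uniform(0,1); with
        # nothing pinning abundance below M, the saturation guard must fire
        traps = make_grid(2, 2, 1.0, K=2, T=3)
        data = EncounterData(y=np.zeros((0, 4, 3), dtype=int), M=20)
        config = FitConfig(movement_model="independent", M=20,
                           state_space=make_state_space(traps, 1.0),
                           n_chains=1, n_iter=6000, n_burnin=500, seed=3)
        with pytest.warns(UserWarning, match="augmented size"):
            post = fit_open_scr(data, traps, config)
        assert post.saturated
        assert post.phi.mean() == pytest.approx(0.5, abs=0.06)
        assert post.phi.std() == pytest.approx(np.sqrt(1 / 12), abs=0.05)

    def test_movement_model_validation(self):
        with pytest.raises(ValueError):
            FitConfig(movement_model="markovian_jump")
        with pytest.raises(ValueError):
            FitConfig(movement_model="brownian")


class TestUnequalIntervals:
    def test_validation(self):
        config = unequal_intervals(FitConfig(), [1.0, 2.0, 1.0, 0.5])
        assert config.delta_t.tolist() == [1.0, 2.0, 1.0, 0.5]
        with pytest.raises(ValueError):
            unequal_intervals(FitConfig(), [1.0, -1.0])

    def test_wrong_length_rejected_at_fit(self, default_dataset):
        sim = default_dataset
        config = FitConfig(movement_model="constant", M=150,
                           state_space=make_state_space(sim.traps, 2.0),
                           delta_t=np.ones(2), n_chains=1, n_iter=300,
                           n_burnin=100)
        with pytest.raises(ValueError, match="delta_t"):
            fit_open_scr(sim.data, sim.traps, config)

    def test_doubling_intervals_square_roots_survival(self, default_dataset):
        """Survival per unit interval reparameterizes as phi^dt."""
        sim = default_dataset
        S = make_state_space(sim.traps, 2.0)
        base = FitConfig(movement_model="constant", M=150, state_space=S,
                         n_chains=1, n_iter=4000, n_burnin=1000, seed=2)
        p1 = fit_open_scr(sim.data, sim.traps, base).phi.mean()
        doubled = unequal_intervals(base, np.full(4, 2.0))
        p2 = fit_open_scr(sim.data, sim.traps, doubled).phi.mean()
        assert p2 == pytest.approx(np.sqrt(p1), abs=0.02)


class TestCJS:
    def test_no_information_before_first_or_after_last_detection(self):
        # every individual first seen in the final period: zero survival info
        traps = make_grid(1, 1, 1.0, K=5, T=3)
        y = np.zeros((4, 1, 3), dtype=int)
        y[:, 0, 2] = 2
        data = EncounterData(y=y, M=4)
        config = FitConfig(movement_model="constant",
                           state_space=make_state_space(traps, 1.0),
                           n_chains=1, n_iter=6000, n_burnin=500, seed=4)
        post = fit_cjs(data, traps, config)
        assert post.phi.mean() == pytest.approx(0.5, abs=0.05)
        assert post.N is None and post.gamma is None

    def test_perfect_detection_high_survival(self):
        traps = make_grid(1, 1, 1.0, K=5, T=5)
        y = np.zeros((3, 1, 5), dtype=int)
        y[:, 0, :] = 5
        data = EncounterData(y=y, M=3)
        config = FitConfig(movement_model="constant",
                           state_space=make_state_space(traps, 1.0),
                           n_chains=1, n_iter=4000, n_burnin=500, seed=4,
                           lambda0_max=50.0)
        post = fit_cjs(data, traps, config)
        # 12 survivals, 0 deaths -> Beta(13, 1), mean 0.93
        assert post.phi.mean() > 0.85


class TestEstimators:
    def test_sklearn_interface(self, default_dataset):
        sim = default_dataset
        est = OpenSCRJollySeber(movement_model="constant", buffer=2.0, M=150,
                                n_chains=2, n_iter=700, n_burnin=200, seed=3)
        params = est.get_params()
        assert params["movement_model"] == "constant"
        est.set_params(n_iter=800)
        est.fit(sim.data, sim.traps)
        assert 0 < est.phi_mean_ < 1
        assert est.posterior_.n_chains == 2
        assert est.rhat_ is not None and "phi" in est.rhat_
        assert est.N_mean_.shape == (5,)
        assert est.summary_.loc["phi", "mean"] == pytest.approx(est.phi_mean_)

    def test_cjs_estimator(self, default_dataset):
        sim = default_dataset
        est = OpenSCRCormackJollySeber(movement_model="constant", buffer=2.0,
                                       n_chains=1, n_iter=600, n_burnin=200,
                                       seed=3)
        est.fit(sim.data, sim.traps)
        assert not hasattr(est, "N_mean_")
        assert 0 < est.phi_mean_ < 1
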