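import numpy as np
import pytest

from svclogit.gibbs import McmcSettings, gibbs_fit, posterior_summary, scalar_draws
from svclogit.graph import build_region_graph
from svclogit.models import ModelSpec, build_design
from svclogit.simulate import SimConfig, simulate_survey

from .conftest import (
    grid_posterior_1d,
    grid_posterior_2d,
    intercept_only_design,
    ks_vs_grid,
    one_covariate_design,
)


class TestSamplerVsGridOracle:
    def test_intercept_only_probability_mean(self):
        # 7 successes in 10: posterior mean of p from the sampler matches the
        # dense 1-D numerical-integration posterior
        y = np.array([1.0] * 7 + [0.0] * 3)
        d = intercept_only_design(y)
        draws = gibbs_fit(d, mcmc=McmcSettings(iters=22000, burnin=2000,
                                               thin=1, seed=3))
        p = 1.0 / (1.0 + np.exp(-draws.params["beta0"]))
        grid, dens = grid_posterior_1d(y)
        oracle = np.trapezoid(dens / (1.0 + np.exp(-grid)), grid)
        assert p.mean() == pytest.approx(oracle, abs=0.05)
        assert p.mean() == pytest.approx(0.7, abs=0.05)

    def test_one_covariate_matches_2d_grid(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(50)
        eta = -0.5 + 1.2 * x
        y = (rng.random(50) < 1 / (1 + np.exp(-eta))).astype(float)
        d = one_covariate_design(y, x)
        draws = gibbs_fit(d, mcmc=McmcSettings(iters=22000, burnin=2000,
                                               thin=1, seed=4))
        g0, g1, dens = grid_posterior_2d(y, x)
        d0, d1 = g0[1] - g0[0], g1[1] - g1[0]
        marg0 = dens.sum(axis=1) * d1
        marg1 = dens.sum(axis=0) * d0
        for chain, grid, marg in ((draws.params["beta0"], g0, marg0),
                                  (draws.params["beta"][:, 0], g1, marg1)):
            om = np.sum(grid * marg) * (grid[1] - grid[0])
            osd = np.sqrt(np.sum(grid**2 * marg) * (grid[1] - grid[0]) - om**2)
            mcse = 3 * osd / np.sqrt(len(chain) / 10)   # generous ESS margin
            assert chain.mean() == pytest.approx(om, abs=max(mcse, 0.05))
            assert chain.std() == pytest.approx(osd, rel=0.1)

    def test_intercept_marginal_ks(self):
        y = np.array([1.0] * 7 + [0.0] * 3)
        d = intercept_only_design(y)
        draws = gibbs_fit(d, mcmc=McmcSettings(iters=27000, burnin=2000,
                                               thin=1, seed=5))
        grid, dens = grid_posterior_1d(y)
        assert ks_vs_grid(draws.params["beta0"], grid, dens) < 0.03


class TestConstraintPreservation:
    def test_every_retained_draw_satisfies_constraints(self):
        cfg = SimConfig(seed=6, n_per_region={
            k: 80 for k in ("EC", "FS", "Gau", "KN", "Lim", "Mp", "NC", "NW", "WC")})
        ds, _ = simulate_survey(cfg)
        spec = ModelSpec.from_id(8, svc_covariates=("sex=Female",))
        d = build_design(ds, spec, cfg.graph)
        draws = gibbs_fit(d, spec, McmcSettings(iters=400, burnin=100, thin=1,
                                                seed=7))
        assert np.max(np.abs(draws.params["s"].sum(axis=1))) < 1e-8
        assert np.max(np.abs(draws.params["f_age"].sum(axis=1))) < 1e-8
        assert np.max(np.abs(draws.params["phi"].sum(axis=2))) < 1e-8

    def test_reproducible_for_seed(self):
        y = np.array([1.0, 0.0, 1.0, 1.0, 0.0] * 4)
        d = intercept_only_design(y)
        mc = McmcSettings(iters=500, burnin=100, thin=2, seed=13)
        a = gibbs_fit(d, mcmc=mc)
        b = gibbs_fit(d, mcmc=mc)
        assert np.array_equal(a.params["beta0"], b.params["beta0"])
        assert a.n_draws == mc.n_retained


class TestPermutationEquivariance:
    def test_region_relabelling_permutes_posterior(self):
        labels = ("EC", "FS", "Gau", "KN", "Lim", "Mp", "NC", "NW", "WC")
        cfg = SimConfig(seed=10, n_per_region={k: 100 for k in labels},
                        svc_columns=(), svc_scale=0.0)
        ds, _ = simulate_survey(cfg)
        spec = ModelSpec.from_id(4)
        d = build_design(ds, spec, cfg.graph)
        mc = McmcSettings(iters=1500, burnin=500, thin=1, seed=11)
        base = posterior_summary(gibbs_fit(d, spec, mc))

        # permute region order consistently in graph and dataset
        perm = np.array([3, 1, 4, 0, 8, 6, 2, 7, 5])
        new_ids = tuple(np.asarray(labels)[perm])
        edges = [(labels[i], labels[j]) for i, j in cfg.graph.edges]
        g2 = build_region_graph(edges, new_ids)
        inv = np.argsort(perm)
        ds2 = ds
        ds2.region_ids = new_ids
        ds2.region_idx = inv[ds.region_idx]
        d2 = build_design(ds2, spec, g2)
        perm_summ = posterior_summary(gibbs_fit(d2, spec, mc))
        for new_pos, lab in enumerate(new_ids):
            assert perm_summ.loc[f"s[{lab}]", "mean"] == pytest.approx(
                base.loc[f"s[{lab}]", "mean"], abs=0.06)


class TestPriorLimitDegeneracy:
    def test_svc_with_tiny_prior_variance_matches_stationary(self):
        # force the CAR deviations to ~0 via an enormous precision prior:
        # Model 7's mu then matches Model 3's beta for that covariate
        from svclogit.models import HyperPriors

        labels = ("EC", "FS", "Gau", "KN", "Lim", "Mp", "NC", "NW", "WC")
        cfg = SimConfig(seed=14, n_per_region={k: 150 for k in labels},
                        svc_columns=(), svc_scale=0.0, age_amplitude=0.0)
        ds, _ = simulate_survey(cfg)
        tight = HyperPriors(tau_shape=1e6, tau_rate=1.0)   # lambda ~ 1e6
        spec7 = ModelSpec.from_id(7, svc_covariates=("sex=Female",), hyper=tight)
        d7 = build_design(ds, spec7, cfg.graph)
        dr7 = gibbs_fit(d7, spec7, McmcSettings(iters=1500, burnin=500, thin=1,
                                                seed=15))
        spec3 = ModelSpec.from_id(3)
        d3 = build_design(ds, spec3, cfg.graph)
        dr3 = gibbs_fit(d3, spec3, McmcSettings(iters=1500, burnin=500, thin=1,
                                                seed=16))
        assert np.max(np.abs(dr7.params["phi"])) < 0.05
        mu = dr7.params["mu_svc"][:, 0]
        i = d3.fixed_names.index("sex=Female")
        beta = dr3.params["beta"][:, i]
        mcse = 3 * (beta.std() / np.sqrt(100) + mu.std() / np.sqrt(100))
        assert mu.mean() == pytest.approx(beta.mean(), abs=max(mcse, 0.08))


class TestPosteriorSummary:
    def test_known_normal_quantiles(self):
        y = np.array([1.0, 0.0])
        d = intercept_only_design(y)
        draws = gibbs_fit(d, mcmc=McmcSettings(iters=300, burnin=100, thin=1,
                                               seed=1))
        draws.params["beta0"] = np.random.default_rng(0).standard_normal(10000)
        draws.deviance = np.zeros(10000)
        summ = posterior_summary(draws)
        row = summ.loc["beta0"]
        assert row["lo95"] == pytest.approx(-1.96, abs=0.08)
        assert row["hi95"] == pytest.approx(1.96, abs=0.08)
        assert row["lo80"] > row["lo95"] and row["hi80"] < row["hi95"]

    def test_constant_draws_zero_width(self):
        y = np.array([1.0, 0.0])
        d = intercept_only_design(y)
        draws = gibbs_fit(d, mcmc=McmcSettings(iters=300, burnin=100, thin=1,
                                               seed=1))
        draws.params["beta0"] = np.full(500, 2.5)
        summ = posterior_summary(draws)
        assert summ.loc["beta0", "lo95"] == summ.loc["beta0", "hi95"] == 2.5

    def test_scalar_chain_names(self):
        cfg = SimConfig(seed=1, n_per_region={
            k: 40 for k in ("EC", "FS", "Gau", "KN", "Lim", "Mp", "NC", "NW", "WC")})
        ds, _ = simulate_survey(cfg)
        spec = ModelSpec.from_id(7, svc_covariates=("sex=Female",))
        d = build_design(ds, spec, cfg.graph)
        draws = gibbs_fit(d, spec, McmcSettings(iters=200, burnin=100, thin=1,
                                                seed=2))
        names = scalar_draws(draws)
        assert "phi[sex=Female,Gau]" in names
        assert "mu_svc[sex=Female]" in names
        assert "s[WC]" in names
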