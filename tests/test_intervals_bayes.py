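"""MCMC bookkeeping, prior recovery, and agreement with brute-force posteriors."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import invgamma, kstest

from saeintervals.bayes import McmcConfig, bayes_intervals, run_mcmc
from saeintervals.drawset import STATE_ID


def test_thinning_bookkeeping_is_exact(small_design):
    X, y, cidx, cids, _ = small_design
    cfg = McmcConfig(iterations=2000, burn_in=200, thin=5, seed=1, ess_floor=0)
    draws = run_mcmc(X, y, cidx, cfg, county_ids=cids)
    assert draws.n_draws == 400
    assert draws.sigma2.shape == (400,)
    assert (draws.sigma2 > 0).all()


def test_iterations_must_divide_by_thin():
    with pytest.raises(ValueError, match="divisible"):
        McmcConfig(iterations=1001, thin=5)
    with pytest.raises(ValueError, match="burn_in"):
        McmcConfig(iterations=1000, burn_in=-1)


def test_prior_recovery_with_likelihood_off():
    """With the likelihood switched off the chain must sample the prior:
    sigma2 draws are InverseGamma(0.01, 0.01) (KS test at alpha = 0.01)."""
    rng = np.random.default_rng(0)
    n, J = 60, 2
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = (rng.random(n) < 0.3).astype(float)
    county = np.arange(n) % J
    cfg = McmcConfig(iterations=500_000, burn_in=5_000, thin=100, seed=3,
                     likelihood_on=False, ess_floor=0)
    draws = run_mcmc(X, y, county, cfg)
    assert draws.n_draws == 5000
    stat = kstest(draws.sigma2, invgamma(a=0.01, scale=0.01).cdf)
    assert stat.pvalue > 0.01
    # beta components are exact prior Gibbs draws when the likelihood is off?
    # no: the live block is a random walk; check its moments loosely instead
    assert abs(np.std(draws.beta[:, 0]) / 100.0 - 1.0) < 0.25


def test_posterior_matches_dense_grid_on_tiny_model():
    """Intercept-only model, two counties, variance component pinned:
    MCMC posterior mean of the intercept vs 3-D grid integration over
    (b0, u1, u2).  Pinning sigma2 keeps the intercept identified, so the
    gold-standard grid is accurate and the tolerance meaningful."""
    rng = np.random.default_rng(12)
    n_per = 15
    s2_fix = 0.25
    county = np.repeat([0, 1], n_per)
    p = expit(-0.4 + np.array([0.3, -0.3])[county])
    y = (rng.random(2 * n_per) < p).astype(float)
    X = np.ones((2 * n_per, 1))
    k = np.array([y[county == 0].sum(), y[county == 1].sum()])
    m = np.array([n_per, n_per], dtype=float)

    b0 = np.linspace(-6, 6, 401)
    u = np.linspace(-6, 6, 401)

    def county_marginal(kk, mm):  # integrate u against N(0, s2_fix) per b0
        from scipy.special import logsumexp

        eta = b0[:, None] + u[None, :]
        ll = kk * eta - mm * np.logaddexp(0.0, eta)
        lp_u = -0.5 * np.log(2 * np.pi * s2_fix) - u**2 / (2 * s2_fix)
        return logsumexp(ll + lp_u[None, :], axis=1)

    post = (county_marginal(k[0], m[0]) + county_marginal(k[1], m[1])
            - b0**2 / (2 * 10_000.0))
    w = np.exp(post - post.max())
    grid_mean = float((b0 * w).sum() / w.sum())

    cfg = McmcConfig(iterations=400_000, burn_in=10_000, thin=20, seed=4,
                     ess_floor=0, fix_sigma2=s2_fix)
    draws = run_mcmc(X, y, county, cfg)
    assert (draws.sigma2 == s2_fix).all()
    assert draws.beta[:, 0].mean() == pytest.approx(grid_mean, abs=0.01)


def test_chains_with_different_seeds_agree(small_design):
    X, y, cidx, cids, _ = small_design
    means, sds, ns = [], [], []
    for seed in (1, 2):
        cfg = McmcConfig(iterations=10_000, burn_in=2_000, thin=5, seed=seed, ess_floor=0)
        d = run_mcmc(X, y, cidx, cfg, county_ids=cids)
        means.append(d.beta.mean(axis=0))
        sds.append(d.beta.std(axis=0))
        ns.append(max(d.min_ess, 50.0))
    mcse = np.sqrt(sds[0]**2 / ns[0] + sds[1]**2 / ns[1])
    assert np.all(np.abs(means[0] - means[1]) < 4 * mcse + 0.02)


def test_degenerate_draws_give_zero_width_intervals(small_world, small_design):
    """All identical draws collapse the credible interval to a point."""
    from saeintervals.bayes import PosteriorDraws

    X, y, cidx, cids, _ = small_design
    M, p = 100, X.shape[1]
    beta = np.tile(np.linspace(-1, 0.5, p), (M, 1))
    re = np.zeros((M, len(cids)))
    draws = PosteriorDraws(beta=beta, re=re, sigma2=np.full(M, 0.1),
                           county_ids=cids, config=McmcConfig(iterations=500, thin=5))
    est = bayes_intervals(draws, small_world.frame)
    np.testing.assert_allclose(est["hi95"] - est["lo95"], 0.0, atol=1e-12)


def test_posterior_means_track_mc_means_on_shared_world(small_world, small_design, small_fit):
    """Diffuse-prior Bayes and the frequentist parameter simulation agree
    on county means up to Monte Carlo error at this sample size."""
    from saeintervals.mc import mc_intervals

    X, y, cidx, cids, _ = small_design
    cfg = McmcConfig(iterations=20_000, burn_in=2_000, thin=5, seed=7, ess_floor=0)
    d = run_mcmc(X, y, cidx, cfg, county_ids=cids)
    est_b = bayes_intervals(d, small_world.frame)
    est_m = mc_intervals(small_fit, small_world.frame, R=1000, seed=8)
    merged = est_b.merge(est_m, on="area_id", suffixes=("_b", "_m"))
    width = (merged["hi95_b"] - merged["lo95_b"]).to_numpy()
    diff = np.abs(merged["mean_b"].to_numpy() - merged["mean_m"].to_numpy())
    assert np.all(diff < 0.5 * width + 0.01)


def test_first_and_second_half_of_chain_agree(small_world, small_design):
    X, y, cidx, cids, _ = small_design
    cfg = McmcConfig(iterations=30_000, burn_in=3_000, thin=5, seed=9, ess_floor=0)
    d = run_mcmc(X, y, cidx, cfg, county_ids=cids)
    if d.min_ess > 1000:
        from saeintervals.bayes import PosteriorDraws

        half = d.n_draws // 2
        d1 = PosteriorDraws(beta=d.beta[:half], re=d.re[:half], sigma2=d.sigma2[:half],
                            county_ids=d.county_ids, config=d.config)
        e_full = bayes_intervals(d, small_world.frame)
        e_half = bayes_intervals(d1, small_world.frame)
        for col in ("lo95", "hi95"):
            assert np.all(np.abs(e_full[col].to_numpy() - e_half[col].to_numpy()) < 0.012)
    est = bayes_intervals(d, small_world.frame)
    assert ((est["lo95"] <= est["mean"]) & (est["mean"] <= est["hi95"])).all()
    assert est[est.area_id == STATE_ID].shape[0] == 1
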