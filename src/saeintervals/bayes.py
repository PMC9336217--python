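"""Hierarchical Bayesian estimation by Metropolis-within-Gibbs MCMC.

Posterior sampled:

    beta_p ~ N(0, 10,000) iid            (diffuse; variance, not SD)
    re_j | sigma2 ~ N(0, sigma2)
    sigma2 ~ InverseGamma(shape 0.01, scale 0.01)
    y_ij | beta, re_j ~ Bernoulli(expit(x_ij . beta + re_j))

Sampler structure, chosen to match the model rather than any particular
software: a random-walk Metropolis update of the whole beta vector with a
preconditioned proposal (covariance from a plain logistic fit, global
scale adapted during burn-in), per-county 1-D updates of re_j (random walk
scaled by the current sigma, with an occasional independence proposal from
the prior to aid mixing across scales), and a conjugate inverse-gamma
Gibbs draw for sigma2 | re.  Adaptation happens during burn-in only, so
the post-burn-in chain is a fixed Markov kernel.

Bookkeeping follows the usual burn-in/thinning convention: after
``burn_in`` discarded iterations the chain runs ``iterations`` more and
every ``thin``-th state is retained, giving exactly iterations/thin draws
(20,000 at the default 100,000/5).  Every retained draw is post-stratified
to county and state prevalences; posterior means and equal-tailed 95%
credible intervals summarise them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .drawset import DrawSet, area_ids_with_state
from .glmm import _Data, ridge_logistic
from .poststrat import PoststratFrame, prevalence_draws

# the variance prior is so heavy-tailed that draws can exceed float range;
# the chain is confined below this ceiling (~0.2% of prior mass, far less
# posterior mass) to keep u and sigma2 finite
_SIGMA2_CEIL = 1e280


@dataclass
class McmcConfig:
    iterations: int = 100_000
    burn_in: int = 10_000
    thin: int = 5
    prior_beta_variance: float = 10_000.0
    prior_invgamma_shape: float = 0.01
    prior_invgamma_scale: float = 0.01
    seed: int = 0
    ess_floor: float = 100.0
    likelihood_on: bool = True  # False samples the prior (testing switch)
    fix_sigma2: float | None = None  # pin the variance component (testing/oracles)

    def __post_init__(self) -> None:
        if self.iterations % self.thin != 0:
            raise ValueError("iterations must be divisible by thin")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


@dataclass
class PosteriorDraws:
    """Retained posterior draws plus chain diagnostics."""

    beta: np.ndarray  # (M, p)
    re: np.ndarray  # (M, J)
    sigma2: np.ndarray  # (M,)
    county_ids: list
    config: McmcConfig
    accept_beta: float = np.nan
    accept_re: float = np.nan
    min_ess: float = np.nan
    low_ess: bool = False

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]


def _min_ess(draws: "PosteriorDraws") -> float:
    import arviz as az

    chains = np.concatenate(
        [draws.beta, draws.re, np.log(draws.sigma2)[:, None]], axis=1
    )[None, :, :]  # (chain, draw, var)
    ess = [float(az.ess(np.ascontiguousarray(chains[:, :, k]))) for k in range(chains.shape[2])]
    return float(np.nanmin(ess))


def _county_level_columns(X: np.ndarray, county: np.ndarray, J: int) -> tuple[np.ndarray, np.ndarray]:
    """Columns of X constant within county, and their county-value matrix.

    These span the directions along which the fixed effects and the random
    intercepts are only separated by the priors (eta is unchanged by
    beta_k += d, u_j -= c_jk d), so a dedicated recentering move is used to
    walk along that ridge.
    """
    first = np.zeros(J, dtype=int)
    first[county[::-1]] = np.arange(X.shape[0])[::-1]
    cols, Cs = [], []
    for k in range(X.shape[1]):
        cj = X[first, k]
        if np.max(np.abs(X[:, k] - cj[county])) < 1e-12:
            cols.append(k)
            Cs.append(cj)
    return np.asarray(cols, dtype=int), (np.column_stack(Cs) if Cs else np.zeros((J, 0)))


def run_mcmc(
    X: np.ndarray,
    y: np.ndarray,
    county_index: np.ndarray,
    config: McmcConfig | None = None,
    county_ids: list | None = None,
) -> PosteriorDraws:
    """Sample the joint posterior of (beta, re, sigma2)."""
    config = config or McmcConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    county = np.asarray(county_index, dtype=int)
    J = int(county.max()) + 1
    if J < 2:
        raise ValueError("need at least 2 counties")
    p = X.shape[1]
    if county_ids is None:
        county_ids = list(range(J))
    data = _Data(X, y, county, J)
    rng = np.random.default_rng(config.seed)

    a0 = config.prior_invgamma_shape
    b0 = config.prior_invgamma_scale
    vb = config.prior_beta_variance

    # beta components whose design column is identically zero (a factor
    # level absent from this survey) have conditional posterior equal to
    # the prior: they are drawn by exact Gibbs and kept out of the
    # random-walk block, whose preconditioner comes from a ridge-stabilised
    # logistic fit (robust to separation of rare levels).
    live = np.flatnonzero(np.abs(data.X).max(axis=0) > 0.0)
    dead = np.setdiff1d(np.arange(p), live)
    if config.likelihood_on:
        beta, prop_cov = ridge_logistic(data.X, data.k, prior_precision=1.0 / vb, trials=data.m)
        L = np.linalg.cholesky(prop_cov[np.ix_(live, live)] + 1e-12 * np.eye(live.size))
    else:
        beta = np.zeros(p)
        L = np.eye(live.size) * np.sqrt(vb) * 0.5
    beta[dead] = 0.0
    u = np.zeros(J)
    sigma2 = 0.25 if config.fix_sigma2 is None else float(config.fix_sigma2)

    def rows_ll(xb: np.ndarray, uu: np.ndarray) -> np.ndarray:
        if not config.likelihood_on:
            return np.zeros(J)
        eta = xb + uu[data.county]
        rows = data.k * eta - data.m * np.logaddexp(0.0, eta)
        return np.add.reduceat(rows, data.starts)

    xb = data.X @ beta if config.likelihood_on else np.zeros(data.m.size)
    llj = rows_ll(xb, u)

    # recentering move along the county-level ridge (likelihood-invariant)
    ridge_cols, C = _county_level_columns(data.X, data.county, J)
    K = ridge_cols.size
    Xr = np.ascontiguousarray(data.X[:, ridge_cols]) if K else None
    CtC = C.T @ C if K else None
    Ct = C.T.copy() if K else None

    ls_beta = np.log(2.38 / np.sqrt(max(live.size, 1)))  # global proposal scale
    ls_u = np.full(J, np.log(1.0))  # per-county step, in units of sigma
    acc_b = acc_u = 0.0
    n_b = n_u = 0
    accw_b, accw_u = 0.0, np.zeros(J)
    blk = 0

    M = config.iterations // config.thin
    out_beta = np.empty((M, p))
    out_re = np.empty((M, J))
    out_s2 = np.empty(M)
    m = 0

    total = config.burn_in + config.iterations
    for it in range(1, total + 1):
        burn = it <= config.burn_in

        # --- beta block (random-walk Metropolis, preconditioned) ---
        prop = beta.copy()
        prop[live] += np.exp(ls_beta) * (L @ rng.standard_normal(live.size))
        # prop is a fresh array; beta is owned by the chain throughout
        xb_prop = data.X @ prop if config.likelihood_on else xb
        llj_prop = rows_ll(xb_prop, u)
        logr = (llj_prop.sum() - llj.sum()
                - (prop @ prop - beta @ beta) / (2.0 * vb))
        if np.log(rng.random()) < logr:
            beta, xb, llj = prop, xb_prop, llj_prop
            acc = 1.0
        else:
            acc = 0.0
        accw_b += acc
        acc_b += acc
        n_b += 1

        # --- re_j updates, vectorised across counties ---
        sig = np.sqrt(sigma2)
        if it % 10 == 0:
            if config.fix_sigma2 is None:
                # scale-group move: (u, sigma2) -> (c u, c^2 sigma2).  With
                # the Haar measure on the multiplicative group, the prior
                # part of the orbit conditional is exactly
                # c^2 ~ InvGamma(a0, b0/sigma2) (the u prior cancels the
                # Jacobian), so c is proposed from it and accepted with the
                # likelihood ratio alone.  This jumps the u--sigma2 funnel
                # across scales in one step.
                g = rng.gamma(a0)
                c2 = (b0 / sigma2) / g if g > 0 else np.inf
                if np.isfinite(c2) and 0.0 < c2 * sigma2 < _SIGMA2_CEIL:
                    c = np.sqrt(c2)
                    u_sc = c * u
                    llj_sc = rows_ll(xb, u_sc)
                    if np.log(rng.random()) < llj_sc.sum() - llj.sum():
                        u, llj, sigma2 = u_sc, llj_sc, c2 * sigma2
                        sig = np.sqrt(sigma2)

            # independence proposal from the prior; prior cancels proposal
            u_prop = sig * rng.standard_normal(J)
            llj_prop = rows_ll(xb, u_prop)
            logr_j = llj_prop - llj
        else:
            u_prop = u + sig * np.exp(ls_u) * rng.standard_normal(J)
            llj_prop = rows_ll(xb, u_prop)
            logr_j = llj_prop - llj + (u**2 - u_prop**2) / (2.0 * sigma2)
        take = np.log(rng.random(J)) < logr_j
        u = np.where(take, u_prop, u)
        llj = np.where(take, llj_prop, llj)
        accw_u += take
        acc_u += take.mean()
        n_u += 1

        # --- recentering: shift county-level betas against the intercepts ---
        # eta (hence the likelihood) is invariant along beta_r += d,
        # u -= C d; the target restricted to that translation orbit is
        # Gaussian in d, so d is drawn exactly and always accepted
        # (a translation-group Gibbs move).
        if K and config.likelihood_on:
            A = CtC / sigma2
            A_diag = A.diagonal() + 1.0 / vb
            b_lin = -beta[ridge_cols] / vb + Ct @ u / sigma2
            if K == 2:
                # closed-form 2x2 sample: d ~ N(A^-1 b, A^-1)
                a11, a22 = A_diag
                a12 = A[0, 1]
                det = a11 * a22 - a12 * a12
                m1 = (a22 * b_lin[0] - a12 * b_lin[1]) / det
                m2 = (a11 * b_lin[1] - a12 * b_lin[0]) / det
                l11 = np.sqrt(a11)
                l21 = a12 / l11
                l22 = np.sqrt(a22 - l21 * l21)
                z1, z2 = rng.standard_normal(2)
                # solve L' e = z for e (upper triangular back-substitution)
                e2 = z2 / l22
                e1 = (z1 - l21 * e2) / l11
                d = np.array([m1 + e1, m2 + e2])
            else:
                Afull = A + np.eye(K) / vb - np.diag(A.diagonal()) + np.diag(A_diag)
                La = np.linalg.cholesky(Afull)
                mean_d = np.linalg.solve(Afull, b_lin)
                d = mean_d + np.linalg.solve(La.T, rng.standard_normal(K))
            beta[ridge_cols] += d
            u = u - C @ d
            xb = xb + Xr @ d

        # --- unidentified beta components: exact Gibbs from the prior ---
        if dead.size:
            beta[dead] = np.sqrt(vb) * rng.standard_normal(dead.size)

        # --- sigma2 | re : conjugate inverse gamma ---
        if config.fix_sigma2 is None:
            shape = a0 + 0.5 * J
            scale = b0 + 0.5 * float(u @ u)
            new_s2 = scale / rng.gamma(shape)
            if 0.0 < new_s2 < _SIGMA2_CEIL:
                sigma2 = new_s2

        # --- burn-in-only adaptation ---
        if burn:
            blk += 1
            if blk == 25:
                delta = min(0.25, 4.0 / np.sqrt(it / 25.0 + 1.0))
                ls_beta += delta if accw_b / 25.0 > 0.30 else -delta
                ls_u += np.where(accw_u / 25.0 > 0.40, delta, -delta)
                accw_b, accw_u = 0.0, np.zeros(J)
                blk = 0
        elif (it - config.burn_in) % config.thin == 0:
            out_beta[m] = beta
            out_re[m] = u
            out_s2[m] = sigma2
            m += 1

    draws = PosteriorDraws(
        beta=out_beta, re=out_re, sigma2=out_s2,
        county_ids=list(county_ids), config=config,
        accept_beta=acc_b / n_b, accept_re=acc_u / n_u,
    )
    draws.min_ess = _min_ess(draws)
    if draws.min_ess < config.ess_floor:
        draws.low_ess = True
        warnings.warn(
            f"minimum effective sample size {draws.min_ess:.0f} below floor "
            f"{config.ess_floor:.0f}; treat intervals with caution"
        )
    return draws


def bayes_intervals(
    draws: PosteriorDraws,
    frame: PoststratFrame,
    return_draws: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, DrawSet]:
    """Post-stratify every retained draw; posterior means and 95% CrIs."""
    if draws.county_ids != list(frame.county_ids):
        raise ValueError("posterior draws and census frame cover different counties")
    values = prevalence_draws(draws.beta, draws.re, frame)
    ds = DrawSet(method="bayes", values=values,
                 area_ids=area_ids_with_state(frame.county_ids),
                 seed=draws.config.seed)
    est = ds.to_estimates()
    return (est, ds) if return_draws else est
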