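"""Random-intercept logistic GLMM fit by maximum marginal likelihood.

The model is

    y_ij | u_j ~ Bernoulli(expit(x_ij . beta + u_j)),   u_j ~ N(0, sigma^2)

with one random intercept per county.  The marginal likelihood integrates
u_j out county by county; because the random effect is one-dimensional the
integral is evaluated with adaptive Gauss-Hermite quadrature: nodes are
centred at the conditional posterior mode of u_j and scaled by the
curvature there, which keeps a modest node count (15 by default) accurate
even when a county contributes hundreds of Bernoulli observations.

Optimisation alternates two steps until the parameters stop moving:
adapt the quadrature grid at the current parameters, then maximise the
fixed-grid approximation with L-BFGS-B using its exact analytic gradient.
Holding the grid fixed inside each inner solve makes the inner gradient
exact, so tight gradient tolerances are attainable; re-adapting outside
restores the accuracy of the adaptive rule.

Empirical best predictors of the random effects (the EBLUPs) are the
conditional posterior modes at the fitted parameters and their prediction
variances come from the curvature at the mode.  The covariance of the
fixed effects is the corresponding block of the inverse observed
information of the marginal log-likelihood (computed by differencing the
analytic gradient), so it propagates the uncertainty in the variance
component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

_SIGMA2_FLOOR = 1e-8  # below this the fit is reported as a boundary (sigma2 = 0)


@dataclass
class GLMMOptions:
    n_quad: int = 15
    max_outer: int = 50
    inner_gtol: float = 1e-8
    inner_ftol: float = 1e-13
    outer_tol: float = 1e-8
    compute_cov: bool = True
    start_beta: np.ndarray | None = None
    start_sigma2: float | None = None
    fix_sigma2: float | None = None  # hold the variance component fixed


@dataclass
class GLMMFit:
    """Everything downstream interval methods need from the fitted model."""

    beta: np.ndarray
    beta_cov: np.ndarray
    sigma2_re: float
    re: np.ndarray  # per-county EBLUP
    re_pred_var: np.ndarray
    county_ids: list
    loglik: float
    converged: bool
    boundary_sigma: bool = False
    n_quad: int = 15
    cross_cov_included: bool = False  # beta-re cross-covariance in eta SEs
    column_names: tuple[str, ...] = ()
    n_obs: int = 0

    def require_converged(self) -> "GLMMFit":
        if not self.converged:
            raise RuntimeError("GLMM fit did not converge; downstream methods refuse it")
        return self

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "beta": self.beta.tolist(),
            "beta_cov": self.beta_cov.tolist(),
            "sigma2_re": self.sigma2_re,
            "re": self.re.tolist(),
            "re_pred_var": self.re_pred_var.tolist(),
            "county_ids": list(self.county_ids),
            "loglik": self.loglik,
            "converged": self.converged,
            "boundary_sigma": self.boundary_sigma,
            "n_quad": self.n_quad,
            "cross_cov_included": self.cross_cov_included,
            "column_names": list(self.column_names),
            "n_obs": self.n_obs,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GLMMFit":
        d = json.loads(Path(path).read_text())
        return cls(
            beta=np.asarray(d["beta"]),
            beta_cov=np.asarray(d["beta_cov"]),
            sigma2_re=float(d["sigma2_re"]),
            re=np.asarray(d["re"]),
            re_pred_var=np.asarray(d["re_pred_var"]),
            county_ids=d["county_ids"],
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
            boundary_sigma=bool(d["boundary_sigma"]),
            n_quad=int(d["n_quad"]),
            cross_cov_included=bool(d["cross_cov_included"]),
            column_names=tuple(d["column_names"]),
            n_obs=int(d["n_obs"]),
        )


@dataclass
class LinearPredictorTable:
    """Per-respondent predicted linear predictor and its standard error."""

    eta: np.ndarray
    se: np.ndarray
    county_index: np.ndarray
    cross_cov_included: bool = False


class _Data:
    """Likelihood-equivalent binomial aggregation of the Bernoulli rows.

    Respondents sharing a county and identical covariate row contribute
    k*eta - m*log(1+e^eta) jointly, so duplicate design rows (the same
    demographic cell within a county) are collapsed into one weighted row:
    m trials, k successes.  Rows are sorted by county so per-county sums
    are contiguous ``reduceat`` segments.  This is exact and typically
    shrinks the working set severalfold.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, county: np.ndarray, J: int):
        counts = np.bincount(county, minlength=J)
        if (counts == 0).any():
            raise ValueError("every county index in 0..J-1 must have observations")
        key = np.column_stack([county.astype(float), X])
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        self.X = np.ascontiguousarray(uniq[:, 1:])
        self.county = uniq[:, 0].astype(int)  # np.unique sorts, county first
        self.m = np.bincount(inv).astype(float)
        self.k = np.bincount(inv, weights=y)
        self.J = J
        self.n_obs = int(y.size)
        seg = np.bincount(self.county, minlength=J)
        self.starts = np.concatenate([[0], np.cumsum(seg)[:-1]])


def _bernoulli_rows(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # y*eta - log(1 + e^eta), stable for large |eta|
    return y * eta - np.logaddexp(0.0, eta)


def _find_modes(
    data: _Data,
    eta0: np.ndarray,
    sigma2: float,
    u0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-county conditional posterior modes and curvatures of u_j.

    Newton iterations, vectorised across counties; the log-integrand is
    strictly concave in u so Newton with step clipping is safe.
    ``eta0`` is the fixed-effect linear predictor on the aggregated rows.
    """
    county, m, k, J = data.county, data.m, data.k, data.J
    u = np.zeros(J) if u0 is None else u0.copy()
    for _ in range(max_iter):
        p = expit(eta0 + u[county])
        g = np.bincount(county, weights=k - m * p, minlength=J) - u / sigma2
        h = np.bincount(county, weights=m * p * (1.0 - p), minlength=J) + 1.0 / sigma2
        step = np.clip(g / h, -4.0, 4.0)
        u += step
        if np.max(np.abs(step)) < tol:
            break
    p = expit(eta0 + u[county])
    h = np.bincount(county, weights=m * p * (1.0 - p), minlength=J) + 1.0 / sigma2
    return u, h


class _Quadrature:
    """A fixed adaptive Gauss-Hermite grid: absolute node locations per county."""

    def __init__(self, modes: np.ndarray, curvatures: np.ndarray, n_quad: int):
        z, w = hermgauss(n_quad)
        s = 1.0 / np.sqrt(curvatures)
        self.nodes = modes[:, None] + np.sqrt(2.0) * s[:, None] * z[None, :]  # (J, Q)
        self.logw = (np.log(w) + z**2)[None, :] + 0.5 * np.log(2.0) + np.log(s)[:, None]
        self.n_quad = n_quad


def _grid_loglik_parts(theta: np.ndarray, data: _Data, quad: _Quadrature):
    """Fixed-grid log-likelihood plus the pieces the gradient needs."""
    beta, tau = theta[:-1], theta[-1]
    sigma2 = np.exp(tau)
    eta0 = data.X @ beta
    E = eta0[:, None] + quad.nodes[data.county]  # (n_agg, Q)
    P = expit(E)
    rows = data.k[:, None] * E - data.m[:, None] * np.logaddexp(0.0, E)
    ll_nodes = np.add.reduceat(rows, data.starts, axis=0)  # (J, Q)
    logphi = -0.5 * np.log(2.0 * np.pi * sigma2) - quad.nodes**2 / (2.0 * sigma2)
    terms = quad.logw + logphi + ll_nodes
    ll_j = logsumexp(terms, axis=1)
    pi = np.exp(terms - ll_j[:, None])  # posterior quadrature weights
    return float(ll_j.sum()), pi, P


def _grid_nll_grad(theta: np.ndarray, data: _Data, quad: _Quadrature):
    ll, pi, P = _grid_loglik_parts(theta, data, quad)
    sigma2 = np.exp(theta[-1])
    pbar = np.einsum("nq,nq->n", pi[data.county], P)
    g_beta = data.X.T @ (data.k - data.m * pbar)
    dldsig2 = np.sum(pi * (quad.nodes**2 / (2.0 * sigma2**2) - 1.0 / (2.0 * sigma2)))
    g_tau = dldsig2 * sigma2
    return -ll, -np.concatenate([g_beta, [g_tau]])


def marginal_loglik(
    beta: np.ndarray,
    sigma2: float,
    X: np.ndarray,
    y: np.ndarray,
    county: np.ndarray,
    n_quad: int = 15,
) -> float:
    """Adaptive-quadrature marginal log-likelihood at arbitrary parameters."""
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y, dtype=float)
    county = np.asarray(county, dtype=int)
    J = int(county.max()) + 1
    eta0 = X @ beta
    if sigma2 < _SIGMA2_FLOOR:
        return float(_bernoulli_rows(y, eta0).sum())
    data = _Data(np.asarray(X, dtype=float), y, county, J)
    modes, curv = _find_modes(data, data.X @ beta, sigma2)
    quad = _Quadrature(modes, curv, n_quad)
    theta = np.concatenate([beta, [np.log(sigma2)]])
    ll, *_ = _grid_loglik_parts(theta, data, quad)
    return ll


def marginal_loglik_grid(
    beta: np.ndarray,
    sigma2: float,
    X: np.ndarray,
    y: np.ndarray,
    county: np.ndarray,
    half_width: float = 12.0,
    n_grid: int = 4001,
) -> float:
    """Brute-force dense-grid marginal log-likelihood.

    Independent oracle for the quadrature: integrates each county's
    integrand on an equally spaced grid over mode +/- half_width posterior
    standard deviations.  Only sensible at small n.
    """
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y, dtype=float)
    county = np.asarray(county, dtype=int)
    J = int(county.max()) + 1
    eta0 = X @ beta
    total = 0.0
    for j in range(J):
        # crude 1-D Newton just to centre the integration window
        mj, yj, ej = 0.0, y[county == j], eta0[county == j]
        for _ in range(50):
            pj = expit(ej + mj)
            step = (np.sum(yj - pj) - mj / sigma2) / (np.sum(pj * (1 - pj)) + 1 / sigma2)
            mj += step
            if abs(step) < 1e-12:
                break
        s = 1.0 / np.sqrt(np.sum(pj * (1 - pj)) + 1 / sigma2)
        us = np.linspace(mj - half_width * s, mj + half_width * s, n_grid)
        mask = county == j
        eta = eta0[mask][:, None] + us[None, :]
        rows = y[mask][:, None] * eta - np.logaddexp(0.0, eta)
        logf = rows.sum(axis=0) - 0.5 * np.log(2.0 * np.pi * sigma2) - us**2 / (2.0 * sigma2)
        du = us[1] - us[0]
        total += logsumexp(logf) + np.log(du)
    return float(total)


_RIDGE_VARIANCE = 1e4  # weak L2 prior variance keeping separated coefficients finite


def ridge_logistic(
    X: np.ndarray,
    y: np.ndarray,
    prior_precision: np.ndarray | float = 1.0 / _RIDGE_VARIANCE,
    max_iter: int = 50,
    tol: float = 1e-10,
    trials: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Logistic regression with a weak L2 penalty, by damped IRLS.

    The penalty (prior variance 10,000 by default) is irrelevant for
    identified coefficients but keeps estimates and curvature finite when a
    factor level is empty or perfectly separated -- which happens routinely
    in resampled or small synthetic surveys with rare race/ethnicity
    groups.  Returns (beta, covariance = inverse penalised information).
    """
    p = X.shape[1]
    m = np.ones(X.shape[0]) if trials is None else np.asarray(trials, dtype=float)
    prec = np.full(p, prior_precision) if np.isscalar(prior_precision) else prior_precision
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(m * mu * (1.0 - mu), 1e-10, None)
        g = X.T @ (y - m * mu) - prec * beta
        H = (X.T * w) @ X + np.diag(prec)
        step = np.linalg.solve(H, g)
        # dampen huge steps far from the optimum
        nrm = np.max(np.abs(step))
        if nrm > 5.0:
            step *= 5.0 / nrm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(m * mu * (1.0 - mu), 1e-10, None)
    H = (X.T * w) @ X + np.diag(prec)
    return beta, _safe_inverse(H)


def _glm_start(data: _Data) -> np.ndarray:
    beta, _ = ridge_logistic(data.X, data.k, trials=data.m)
    return beta


def fit_glmm(
    X: np.ndarray,
    y: np.ndarray,
    county_index: np.ndarray,
    county_ids: list | None = None,
    options: GLMMOptions | None = None,
    column_names: tuple[str, ...] = (),
) -> GLMMFit:
    """Fit the random-intercept logistic model by marginal ML.

    Requires >= 2 counties and binary outcomes.  A variance-component
    estimate at the boundary (sigma2 -> 0) is allowed and flagged; outright
    optimiser failure (after one restart from a perturbed start) yields a
    fit with ``converged=False`` that downstream methods refuse.
    """
    opt = options or GLMMOptions()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    county = np.asarray(county_index, dtype=int)
    J = int(county.max()) + 1
    if J < 2:
        raise ValueError("need at least 2 counties")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary")
    if county_ids is None:
        county_ids = list(range(J))

    # column scaling improves L-BFGS conditioning (poverty is on a 0-100 scale)
    scale = np.maximum(np.abs(X).max(axis=0), 1e-12)
    data = _Data(X / scale, y, county, J)

    beta0 = opt.start_beta * scale if opt.start_beta is not None else _glm_start(data)
    sigma2_0 = opt.start_sigma2 if opt.start_sigma2 is not None else 0.25
    if opt.fix_sigma2 is not None:
        sigma2_0 = max(opt.fix_sigma2, _SIGMA2_FLOOR)
    theta = np.concatenate([beta0, [np.log(max(sigma2_0, _SIGMA2_FLOOR))]])

    p = X.shape[1]
    if opt.fix_sigma2 is not None:
        tau_fix = np.log(max(opt.fix_sigma2, _SIGMA2_FLOOR))
        bounds = [(None, None)] * p + [(tau_fix, tau_fix)]
    else:
        bounds = [(None, None)] * p + [(np.log(_SIGMA2_FLOOR), 8.0)]
    # weak ridge (prior variance 1e4 on the original scale) keeps empty or
    # separated factor levels finite without affecting identified estimates
    prec = np.concatenate([1.0 / (_RIDGE_VARIANCE * scale**2), [0.0]])

    def penalized(theta_cur, data_, quad_):
        nll, grad = _grid_nll_grad(theta_cur, data_, quad_)
        nll += 0.5 * float(prec @ theta_cur**2)
        grad = grad + prec * theta_cur
        return nll, grad

    def solve_from(theta_init: np.ndarray):
        theta_cur = theta_init.copy()
        res, quad = None, None
        for _ in range(opt.max_outer):
            sigma2 = np.exp(theta_cur[-1])
            modes, curv = _find_modes(data, data.X @ theta_cur[:-1], sigma2)
            quad = _Quadrature(modes, curv, opt.n_quad)
            res = minimize(
                penalized, theta_cur, args=(data, quad),
                jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 200, "ftol": opt.inner_ftol, "gtol": opt.inner_gtol},
            )
            moved = np.max(np.abs(res.x - theta_cur))
            theta_cur = res.x
            if moved < opt.outer_tol:
                break
        grad_ok = res is not None and np.max(np.abs(res.jac[:-1])) < 1e-3
        return theta_cur, bool(res.success or grad_ok), quad

    theta_hat, ok, quad = solve_from(theta)
    if not ok:
        rng = np.random.default_rng(0)
        theta_hat2, ok2, quad2 = solve_from(theta + rng.normal(0, 0.1, theta.size))
        if ok2:
            theta_hat, ok, quad = theta_hat2, ok2, quad2

    beta_hat_s = theta_hat[:-1]
    sigma2_hat = float(np.exp(theta_hat[-1]))
    boundary = sigma2_hat <= _SIGMA2_FLOOR * 1.01

    modes, curv = _find_modes(data, data.X @ beta_hat_s, max(sigma2_hat, _SIGMA2_FLOOR))
    re_pred_var = 1.0 / curv
    quad_h = _Quadrature(modes, curv, opt.n_quad)
    theta_at = np.concatenate([beta_hat_s, [np.log(max(sigma2_hat, _SIGMA2_FLOOR))]])
    ll, _, _ = _grid_loglik_parts(theta_at, data, quad_h)

    if opt.compute_cov:
        H = _numeric_hessian(theta_at, data, quad_h) + np.diag(prec)
        cov_all = _safe_inverse(H)
        beta_cov_s = cov_all[:p, :p]
    else:
        beta_cov_s = np.zeros((p, p))

    beta_hat = beta_hat_s / scale
    beta_cov = beta_cov_s / np.outer(scale, scale)
    if boundary:
        sigma2_hat = 0.0

    return GLMMFit(
        beta=beta_hat,
        beta_cov=beta_cov,
        sigma2_re=sigma2_hat,
        re=modes,
        re_pred_var=re_pred_var,
        county_ids=list(county_ids),
        loglik=float(ll),
        converged=bool(ok),
        boundary_sigma=bool(boundary),
        n_quad=opt.n_quad,
        cross_cov_included=False,
        column_names=tuple(column_names),
        n_obs=int(y.size),
    )


def _numeric_hessian(theta: np.ndarray, data: _Data, quad: _Quadrature, h: float = 1e-5):
    """Observed information by central differencing the analytic gradient."""
    d = theta.size
    H = np.zeros((d, d))
    for k in range(d):
        hk = h * max(1.0, abs(theta[k]))
        tp = theta.copy(); tp[k] += hk
        tm = theta.copy(); tm[k] -= hk
        _, gp = _grid_nll_grad(tp, data, quad)
        _, gm = _grid_nll_grad(tm, data, quad)
        H[k] = (gp - gm) / (2.0 * hk)
    return 0.5 * (H + H.T)


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    """Inverse of the information; eigenvalue-clipped if not positive definite."""
    try:
        L = np.linalg.cholesky(H)
        I = np.eye(H.shape[0])
        Linv = np.linalg.solve(L, I)
        return Linv.T @ Linv
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(H)
        w = np.clip(w, 1e-10 * max(w.max(), 1.0), None)
        return (V / w) @ V.T


def linear_predictor_se(
    fit: GLMMFit,
    X: np.ndarray,
    county_index: np.ndarray,
) -> LinearPredictorTable:
    """Predicted linear predictor eta_ij and its standard error per respondent.

    se^2 = x_i' cov(beta) x_i + predvar(u_j); the beta-random-effect
    cross-covariance is not produced by this fitter, so it contributes 0
    (recorded on the table).  A degenerate fit with all-zero uncertainty is
    rejected.
    """
    fit.require_converged()
    county = np.asarray(county_index, dtype=int)
    if county.max() >= len(fit.re):
        raise ValueError("county index outside the fitted counties")
    eta = X @ fit.beta + fit.re[county]
    var = np.einsum("ij,jk,ik->i", X, fit.beta_cov, X) + fit.re_pred_var[county]
    if np.any(var <= 0.0):
        raise ValueError("degenerate fit: non-positive linear-predictor variance")
    return LinearPredictorTable(
        eta=eta, se=np.sqrt(var), county_index=county,
        cross_cov_included=False,
    )
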