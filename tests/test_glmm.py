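"""Marginal-likelihood GLMM fitter against brute-force and external oracles."""

import shutil
import subprocess
import textwrap
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from saeintervals.design import DesignSpec, build_design
from saeintervals.glmm import (
    GLMMOptions,
    fit_glmm,
    linear_predictor_se,
    marginal_loglik,
    marginal_loglik_grid,
    ridge_logistic,
)
from saeintervals.synthetic import GeneratorConfig, generate_world


def test_quadrature_matches_dense_grid_on_tiny_instance(tiny_world):
    """15-node adaptive quadrature vs a 4001-point integration grid."""
    X, y, cidx, _ = build_design(tiny_world.survey, tiny_world.covariates)
    beta = np.zeros(X.shape[1])
    beta[0], beta[-1] = -1.0, 0.01
    for sigma2 in (0.04, 0.25, 1.0, 4.0):
        lq = marginal_loglik(beta, sigma2, X, y, cidx)
        lg = marginal_loglik_grid(beta, sigma2, X, y, cidx)
        assert lq == pytest.approx(lg, abs=1e-4)


def test_quadrature_matches_grid_at_fitted_parameters(tiny_world):
    X, y, cidx, ids = build_design(tiny_world.survey, tiny_world.covariates)
    fit = fit_glmm(X, y, cidx, ids, options=GLMMOptions(compute_cov=False))
    s2 = max(fit.sigma2_re, 1e-4)
    assert marginal_loglik(fit.beta, s2, X, y, cidx) == pytest.approx(
        marginal_loglik_grid(fit.beta, s2, X, y, cidx), abs=1e-4)


def test_no_random_effect_reduces_to_plain_logistic():
    """sigma_re = 0 data, one covariate: the GLMM matches plain logistic
    regression (the exact model here) and recovers truth within 3 SEs."""
    rng = np.random.default_rng(8)
    n = 5000
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    b_true = np.array([-1.5, 0.7])
    y = (rng.random(n) < expit(X @ b_true)).astype(float)
    county = rng.integers(0, 10, n)
    fit = fit_glmm(X, y, county)
    b_glm, cov_glm = ridge_logistic(X, y, prior_precision=1e-10)
    se = np.sqrt(np.diag(fit.beta_cov))
    assert np.all(np.abs(fit.beta - b_true) < 3 * se)
    np.testing.assert_allclose(fit.beta, b_glm, atol=5e-3)
    assert fit.sigma2_re < 0.01


def test_duplicating_counties_doubles_information():
    """Cloning every county (new ids, same rows) leaves beta unchanged and
    halves its covariance: the marginal likelihood doubles exactly."""
    w = generate_world(GeneratorConfig(n_counties=6, n_per_county=100, seed=17,
                                       age_levels=4, race_levels=3,
                                       prevalence_preset="arthritis"))
    spec = DesignSpec(age_levels=4, race_levels=3)
    X, y, cidx, _ = build_design(w.survey, w.covariates, spec)
    J = cidx.max() + 1
    X2 = np.vstack([X, X])
    y2 = np.concatenate([y, y])
    c2 = np.concatenate([cidx, cidx + J])
    f1 = fit_glmm(X, y, cidx)
    f2 = fit_glmm(X2, y2, c2)
    np.testing.assert_allclose(f2.beta, f1.beta, atol=5e-4)
    assert f2.sigma2_re == pytest.approx(f1.sigma2_re, abs=5e-4)
    np.testing.assert_allclose(np.diag(f2.beta_cov), 0.5 * np.diag(f1.beta_cov), rtol=0.02)


def test_eblups_shrink_toward_zero(small_fit, small_design):
    """|EBLUP| never exceeds the unshrunk county effect (prior off)."""
    X, y, cidx, _, _ = small_design
    eta_fixed = X @ small_fit.beta
    raw = np.zeros(len(small_fit.re))
    for j in range(len(raw)):
        m = cidx == j
        ej, yj, uj = eta_fixed[m], y[m], 0.0
        for _ in range(100):  # ML county offset, no prior
            p = expit(ej + uj)
            step = np.sum(yj - p) / max(np.sum(p * (1 - p)), 1e-12)
            uj += np.clip(step, -3, 3)
            if abs(step) < 1e-10:
                break
        raw[j] = uj
    assert np.all(np.abs(small_fit.re) <= np.abs(raw) + 1e-8)
    assert np.all(small_fit.re * raw >= -1e-8)  # same sign


def test_linear_predictor_se_components(small_fit, small_design):
    X, y, cidx, _, _ = small_design
    lp = linear_predictor_se(small_fit, X, cidx)
    np.testing.assert_allclose(lp.eta, X @ small_fit.beta + small_fit.re[cidx])
    assert np.all(lp.se > 0)
    # with a zero cross term, se^2 is at least the county prediction variance
    assert np.all(lp.se**2 >= small_fit.re_pred_var[cidx] - 1e-12)
    assert not lp.cross_cov_included


def test_linear_predictor_rejects_degenerate_fit(small_fit, small_design):
    X, _, cidx, _, _ = small_design
    degenerate = replace(small_fit,
                         beta_cov=np.zeros_like(small_fit.beta_cov),
                         re_pred_var=np.zeros_like(small_fit.re_pred_var))
    with pytest.raises(ValueError, match="degenerate"):
        linear_predictor_se(degenerate, X, cidx)


def test_linear_predictor_se_grows_with_random_effect_variance(small_design):
    """The same data refit with the variance component pinned near zero
    yields smaller linear-predictor SEs than a fit with it pinned high."""
    X, y, cidx, ids, _ = small_design
    lo = fit_glmm(X, y, cidx, ids, options=GLMMOptions(fix_sigma2=1e-6))
    hi = fit_glmm(X, y, cidx, ids, options=GLMMOptions(fix_sigma2=1.0))
    se_lo = linear_predictor_se(lo, X, cidx).se
    se_hi = linear_predictor_se(hi, X, cidx).se
    assert np.median(se_hi) > np.median(se_lo)


def test_unconverged_fit_is_refused(small_fit):
    bad = replace(small_fit, converged=False)
    with pytest.raises(RuntimeError, match="did not converge"):
        bad.require_converged()


def test_fit_requires_two_counties_and_binary_outcomes():
    X = np.ones((10, 1))
    with pytest.raises(ValueError, match="2 counties"):
        fit_glmm(X, np.zeros(10), np.zeros(10, dtype=int))
    with pytest.raises(ValueError, match="binary"):
        fit_glmm(X, np.full(10, 0.5), np.arange(10) % 2)


def test_fit_roundtrips_through_json(small_fit, tmp_path):
    path = tmp_path / "fit.json"
    small_fit.to_json(path)
    back = type(small_fit).from_json(path)
    np.testing.assert_allclose(back.beta, small_fit.beta)
    np.testing.assert_allclose(back.beta_cov, small_fit.beta_cov)
    assert back.county_ids == small_fit.county_ids
    assert back.converged == small_fit.converged


def test_matches_lme4_on_moderate_dataset(tmp_path):
    """Independent cross-check: R lme4 glmer with adaptive quadrature on the
    same data agrees on the fixed effects and the variance component."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript unavailable; cannot run the lme4 cross-check")
    w = generate_world(GeneratorConfig(
        n_counties=12, n_per_county=100, seed=31, sigma_re=0.6,
        age_levels=4, race_levels=3, prevalence_preset="arthritis"))
    X, y, cidx, ids = build_design(
        w.survey, w.covariates, spec=DesignSpec(age_levels=4, race_levels=3))
    fit = fit_glmm(X, y, cidx, ids)
    df = w.survey[["county_id", "age_group", "sex", "race_eth", "outcome"]].copy()
    df["poverty"] = w.survey["county_id"].map(
        w.covariates.set_index("county_id")["poverty_pct"])
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rscript = textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$age_group <- factor(d$age_group); d$sex <- factor(d$sex)
        d$race_eth <- factor(d$race_eth)
        m <- glmer(outcome ~ age_group + sex + race_eth + poverty + (1|county_id),
                   data=d, family=binomial, nAGQ=15)
        cat(c(fixef(m), as.numeric(VarCorr(m)$county_id)), sep="\\n")
    """)
    out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                         text=True, check=True, timeout=300)
    vals = np.array([float(v) for v in out.stdout.split()])
    beta_r, sigma2_r = vals[:-1], vals[-1]
    np.testing.assert_allclose(fit.beta, beta_r, atol=0.02)
    assert fit.sigma2_re == pytest.approx(sigma2_r, abs=0.02, rel=0.1)
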