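"""Parametric and county-stratified non-parametric bootstrap intervals.

Parametric: from the base fit, each respondent's linear predictor gets a
normal perturbation eta* ~ N(eta_hat, se^2) drawn independently per
respondent, a new outcome y* ~ Bernoulli(expit(eta*)) is generated, the
model is refit on (X, y*), and the refit is post-stratified.  Note that
drawing eta* independently across respondents averages the shared county-
effect uncertainty away within a county, which is why this scheme produces
conspicuously narrower county intervals than the alternatives.

Non-parametric: respondents are resampled with replacement within county,
keeping every county's sample size exactly equal to the original, then the
model is refit on the resample and post-stratified.

Either way, B replicate prevalence vectors form the draw matrix from which
percentile intervals are read.  Replicate r uses the deterministic
sub-seed (master seed, r), so results are independent of execution order
and any subset of replicates is reproducible.  Refits warm-start at the
base fit; non-converged refits are dropped and counted against a failure
policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import DesignSpec, build_design
from .drawset import DrawSet, area_ids_with_state
from .glmm import GLMMFit, GLMMOptions, LinearPredictorTable, fit_glmm, linear_predictor_se
from .poststrat import PoststratFrame, area_prevalence, build_frame


@dataclass
class BootstrapConfig:
    B: int = 1000
    mode: str = "parametric"  # or "nonparametric"
    seed: int = 0
    max_fail_fraction: float = 0.02
    refit_options: GLMMOptions | None = None

    def __post_init__(self) -> None:
        if self.B < 40:
            raise ValueError("B must be >= 40 for 2.5/97.5 percentile intervals")
        if self.mode not in ("parametric", "nonparametric"):
            raise ValueError(f"unknown bootstrap mode {self.mode!r}")


def _replicate_rng(master_seed: int, r: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((master_seed, r)))


def _refit_options(base: GLMMFit, user: GLMMOptions | None) -> GLMMOptions:
    if user is not None:
        return user
    # replicate-to-replicate Monte Carlo noise dwarfs 1e-6 parameter error,
    # so refits run with looser tolerances than the base fit
    return GLMMOptions(
        compute_cov=False,
        start_beta=base.beta,
        start_sigma2=max(base.sigma2_re, 1e-3),
        n_quad=7,
        inner_gtol=1e-6,
        inner_ftol=1e-10,
        outer_tol=1e-6,
        max_outer=5,
    )


def parametric_replicate(
    lp: LinearPredictorTable,
    X: np.ndarray,
    county_index: np.ndarray,
    frame: PoststratFrame,
    seed_pair: tuple[int, int],
    refit_options: GLMMOptions,
) -> tuple[np.ndarray, bool]:
    """One parametric replicate: perturb eta, regenerate outcomes, refit."""
    rng = np.random.default_rng(np.random.SeedSequence(seed_pair))
    eta_star = lp.eta + lp.se * rng.standard_normal(lp.eta.size)
    p_star = expit(eta_star)
    y_star = (rng.random(p_star.size) < p_star).astype(float)
    refit = fit_glmm(X, y_star, county_index, options=refit_options)
    if not refit.converged:
        return np.full(frame.n_counties + 1, np.nan), False
    county, state = area_prevalence(refit.beta, refit.re, frame)
    return np.concatenate([county, [state]]), True


def nonparametric_replicate(
    X: np.ndarray,
    y: np.ndarray,
    county_index: np.ndarray,
    frame: PoststratFrame,
    seed_pair: tuple[int, int],
    refit_options: GLMMOptions,
) -> tuple[np.ndarray, bool]:
    """One stratified replicate: resample within county, refit.

    Each county contributes exactly its original number of respondents.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed_pair))
    idx = np.arange(y.size)
    take = np.empty(y.size, dtype=int)
    pos = 0
    for j in range(frame.n_counties):
        rows = idx[county_index == j]
        take[pos:pos + rows.size] = rng.choice(rows, size=rows.size, replace=True)
        pos += rows.size
    refit = fit_glmm(X[take], y[take], county_index[take], options=refit_options)
    if not refit.converged:
        return np.full(frame.n_counties + 1, np.nan), False
    county, state = area_prevalence(refit.beta, refit.re, frame)
    return np.concatenate([county, [state]]), True


def bootstrap_intervals(
    survey: pd.DataFrame,
    covariates: pd.DataFrame,
    census: pd.DataFrame,
    config: BootstrapConfig,
    base_fit: GLMMFit | None = None,
    spec: DesignSpec | None = None,
    return_draws: bool = False,
):
    """Bootstrap estimates and 95% intervals for every area.

    Runs B replicates with per-replicate sub-seeds (order invariant),
    drops non-converged refits, and aborts if the failure fraction exceeds
    the configured policy.  Returns the estimate table, and optionally the
    DrawSet plus a small info dict with the failure count.
    """
    spec = spec or DesignSpec()
    X, y, county_index, county_ids = build_design(survey, covariates, spec)
    frame = build_frame(census, covariates, spec)
    if list(frame.county_ids) != list(county_ids):
        raise ValueError("survey and census cover different counties")
    if base_fit is None:
        base_fit = fit_glmm(X, y, county_index, county_ids, column_names=spec.column_names)
    base_fit.require_converged()
    opts = _refit_options(base_fit, config.refit_options)

    if config.mode == "parametric":
        lp = linear_predictor_se(base_fit, X, county_index)
        run = lambda r: parametric_replicate(lp, X, county_index, frame, (config.seed, r), opts)
    else:
        run = lambda r: nonparametric_replicate(X, y, county_index, frame, (config.seed, r), opts)

    rows, failed = [], 0
    for r in range(config.B):
        vec, ok = run(r)
        if ok:
            rows.append(vec)
        else:
            failed += 1
    if failed > config.max_fail_fraction * config.B:
        raise RuntimeError(
            f"{failed}/{config.B} bootstrap refits failed to converge "
            f"(policy allows {config.max_fail_fraction:.0%})"
        )
    values = np.vstack(rows)
    draws = DrawSet(method="parboot" if config.mode == "parametric" else "npboot",
                    values=values, area_ids=area_ids_with_state(frame.county_ids),
                    seed=config.seed)
    est = draws.to_estimates()
    info = {"n_failed": failed, "n_used": len(rows)}
    return (est, draws, info) if return_draws else est
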