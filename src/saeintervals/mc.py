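"""Monte Carlo simulation intervals.

The cheapest of the interval constructions: no refitting.  Parameters are
drawn from their estimated sampling distributions -- beta* from a
multivariate normal centred at the estimate with the full estimated
covariance, and each county effect re_j* from an independent normal at its
EBLUP with its prediction variance -- and every draw is post-stratified.
The per-area mean and the 2.5th/97.5th order statistics of the R = 1000
simulated prevalences give the estimate and its 95% interval.

Drawing beta jointly (rather than component-wise) preserves the covariance
of the fixed effects in any functional of beta; beta and re draws are
mutually independent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .drawset import DrawSet, area_ids_with_state
from .glmm import GLMMFit
from .poststrat import PoststratFrame, prevalence_draws


def _covariance_factor(cov: np.ndarray) -> np.ndarray:
    """A factor L with L L' = cov; eigenvalue-clipped when cov is singular."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular beta covariance; clipping negative eigenvalues")
        w, V = np.linalg.eigh(cov)
        return V * np.sqrt(np.clip(w, 0.0, None))


def draw_parameters(
    fit: GLMMFit, R: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """R independent draws of (beta*, re*) from the estimated distributions."""
    fit.require_converged()
    rng = np.random.default_rng(seed)
    L = _covariance_factor(fit.beta_cov)
    beta_draws = fit.beta[None, :] + rng.standard_normal((R, fit.beta.size)) @ L.T
    re_draws = fit.re[None, :] + rng.standard_normal((R, fit.re.size)) * np.sqrt(fit.re_pred_var)[None, :]
    return beta_draws, re_draws


def mc_intervals(
    fit: GLMMFit,
    frame: PoststratFrame,
    R: int = 1000,
    seed: int = 0,
    return_draws: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, DrawSet]:
    """Parameter-simulation estimates and 95% intervals for every area."""
    if R < 40:
        raise ValueError("R must be >= 40 for 2.5/97.5 percentile intervals")
    if fit.county_ids != list(frame.county_ids):
        raise ValueError("fit and census frame cover different counties")
    beta_draws, re_draws = draw_parameters(fit, R, seed)
    values = prevalence_draws(beta_draws, re_draws, frame)
    draws = DrawSet(method="mc", values=values,
                    area_ids=area_ids_with_state(frame.county_ids), seed=seed)
    est = draws.to_estimates()
    return (est, draws) if return_draws else est
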