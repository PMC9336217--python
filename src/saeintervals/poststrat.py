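"""Post-stratification: from model parameters to area prevalences.

Given fixed effects ``beta`` and county random intercepts ``re``, the
predicted probability for census cell k in county j is

    p_kj = expit(X_k . beta + re_j)

and the county and state prevalences are census-count-weighted means

    P_county(j) = sum_k p_kj N_kj / sum_k N_kj
    P_state     = sum_j sum_k p_kj N_kj / sum_j sum_k N_kj

so the state estimate equals the population-weighted mean of the county
estimates.  Cells with zero census count are dropped.  The core is pure
NumPy so the interval methods can post-stratify thousands of parameter
draws cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import DesignSpec, encode_rows


@dataclass
class PoststratFrame:
    """Pre-encoded census frame: one row per populated cell."""

    X: np.ndarray  # (n_cells, p) design rows
    counts: np.ndarray  # (n_cells,) census counts N_kj > 0
    county_index: np.ndarray  # (n_cells,) 0-based county codes
    county_ids: list  # code -> county_id, sorted
    spec: DesignSpec

    @property
    def n_counties(self) -> int:
        return len(self.county_ids)

    @property
    def county_totals(self) -> np.ndarray:
        return np.bincount(self.county_index, weights=self.counts, minlength=self.n_counties)


def build_frame(
    census: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: DesignSpec | None = None,
) -> PoststratFrame:
    """Encode the census table into a prediction-ready frame.

    ``census`` has columns county_id, age_group, sex, race_eth, population;
    ``covariates`` maps county_id to poverty_pct.  Zero-population cells are
    dropped; a county whose total population is zero is an error.
    """
    spec = spec or DesignSpec()
    cells = census[census["population"] > 0].reset_index(drop=True)
    county_ids = sorted(census["county_id"].unique().tolist())
    empty = set(county_ids) - set(cells["county_id"])
    if empty:
        raise ValueError(f"counties with zero total population: {sorted(empty)}")
    cov = covariates.set_index("county_id")["poverty_pct"]
    missing = set(county_ids) - set(cov.index)
    if missing:
        raise ValueError(f"counties without covariate rows: {sorted(missing)}")
    code = {c: i for i, c in enumerate(county_ids)}
    county_index = cells["county_id"].map(code).to_numpy()
    X = encode_rows(
        cells["age_group"].to_numpy(),
        cells["sex"].to_numpy(),
        cells["race_eth"].to_numpy(),
        cells["county_id"].map(cov).to_numpy(dtype=float),
        spec,
    )
    return PoststratFrame(
        X=X,
        counts=cells["population"].to_numpy(dtype=float),
        county_index=county_index,
        county_ids=county_ids,
        spec=spec,
    )


def cell_probabilities(beta: np.ndarray, re: np.ndarray, frame: PoststratFrame) -> np.ndarray:
    """Predicted probability for every populated cell (strictly inside (0,1))."""
    beta = np.asarray(beta, dtype=float)
    re = np.asarray(re, dtype=float)
    if beta.shape[0] != frame.X.shape[1]:
        raise ValueError(f"beta has {beta.shape[0]} entries, design has {frame.X.shape[1]} columns")
    if re.shape[0] != frame.n_counties:
        raise ValueError(f"re covers {re.shape[0]} counties, frame has {frame.n_counties}")
    eta = frame.X @ beta + re[frame.county_index]
    p = expit(eta)
    # keep probabilities strictly interior for downstream logs/intervals
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)


def aggregate(p_cells: np.ndarray, frame: PoststratFrame) -> tuple[np.ndarray, float]:
    """Census-weighted county prevalences and the state prevalence."""
    num = np.bincount(frame.county_index, weights=p_cells * frame.counts, minlength=frame.n_counties)
    den = frame.county_totals
    county = num / den
    state = float(num.sum() / den.sum())
    return county, state


def area_prevalence(beta: np.ndarray, re: np.ndarray, frame: PoststratFrame) -> tuple[np.ndarray, float]:
    """Convenience: cell probabilities then aggregation in one call."""
    return aggregate(cell_probabilities(beta, re, frame), frame)


def prevalence_draws(
    beta_draws: np.ndarray,
    re_draws: np.ndarray,
    frame: PoststratFrame,
    chunk: int = 256,
) -> np.ndarray:
    """Post-stratify many parameter draws at once.

    ``beta_draws`` is (R, p) and ``re_draws`` is (R, J); returns an
    (R, J + 1) array whose last column is the state prevalence.  Draws are
    processed in chunks to bound memory.
    """
    beta_draws = np.atleast_2d(np.asarray(beta_draws, dtype=float))
    re_draws = np.atleast_2d(np.asarray(re_draws, dtype=float))
    R = beta_draws.shape[0]
    if re_draws.shape[0] != R:
        raise ValueError("beta_draws and re_draws must have the same number of draws")
    J = frame.n_counties
    out = np.empty((R, J + 1))
    den = frame.county_totals
    wtot = den.sum()
    for lo in range(0, R, chunk):
        hi = min(lo + chunk, R)
        eta = frame.X @ beta_draws[lo:hi].T  # (cells, r)
        eta += re_draws[lo:hi].T[frame.county_index, :]
        p = expit(eta)
        wp = p * frame.counts[:, None]
        for c, r in enumerate(range(lo, hi)):
            num = np.bincount(frame.county_index, weights=wp[:, c], minlength=J)
            out[r, :J] = num / den
            out[r, J] = num.sum() / wtot
    return out
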