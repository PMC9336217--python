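"""Synthetic survey worlds with known ground truth.

Emulates the structure of a state BRFSS-like study: ~67 counties, a target
of ~500 completed interviews per county, respondents classified into
13 age x 2 sex x 8 race/ethnicity post-stratification cells (208 per
county), one county-level poverty covariate, and a binary outcome generated
from a random-intercept logistic model

    P(Y_ij = 1) = expit(X_i . beta + re_j),   re_j ~ N(0, sigma_re^2).

Prevalence presets place the population prevalence near three outcomes of
different magnitude: COPD (7.6%), binge drinking (17.6%) and arthritis
(26.0%).  The preset fixes the non-intercept coefficients at plausible
values and solves the intercept on the generated census frame (with re = 0)
so the post-stratified population prevalence hits the target; the county
random effects then perturb it slightly.

County demographic compositions are drawn from a Dirichlet-multinomial
around a common base composition, so counties differ realistically; the
exact per-county and state prevalences implied by the generating parameters
are computed by the same post-stratification formulas the estimators use
and returned as :class:`AreaTruth` for coverage evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .design import AGE_LEVELS, RACE_LEVELS, SEX_LEVELS, DesignSpec, encode_rows
from .poststrat import PoststratFrame, area_prevalence, build_frame

PRESET_TARGETS = {"copd": 0.076, "binge": 0.176, "arthritis": 0.260}

# Non-intercept coefficients per preset, ordered as DesignSpec columns
# (age_2..age_13, sex_2, race_2..race_8, poverty).  Age gradients rise for
# the chronic conditions and fall for binge drinking; poverty is per
# percentage point below 150% of the poverty line.
_PRESET_SLOPES = {
    "copd": [0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 1.9, 2.0, 2.0,
             0.1,
             0.1, 0.4, -0.6, 0.1, 0.2, 0.3, -0.3,
             0.02],
    "binge": [0.3, 0.2, 0.0, -0.2, -0.4, -0.6, -0.8, -1.0, -1.3, -1.6, -2.0, -2.5,
              -0.8,
              -0.3, 0.1, -0.7, 0.0, -0.2, -0.1, -0.1,
              -0.005],
    "arthritis": [0.3, 0.6, 0.9, 1.2, 1.5, 1.8, 2.1, 2.4, 2.6, 2.8, 2.9, 3.0,
                  0.3,
                  0.1, 0.3, -0.5, 0.0, 0.2, 0.2, -0.2,
                  0.015],
}

# Base adult composition the Dirichlet draws vary around (normalised in code).
_BASE_AGE = np.array([0.13, 0.09, 0.09, 0.08, 0.08, 0.08, 0.085, 0.09, 0.09,
                      0.08, 0.06, 0.045, 0.04])
_BASE_SEX = np.array([0.48, 0.52])
_BASE_RACE = np.array([0.55, 0.15, 0.005, 0.025, 0.002, 0.015, 0.02, 0.233])


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic world.

    ``n_per_county`` may be a single target or a per-county vector.
    ``concentration`` controls the Dirichlet spread of county demographic
    compositions (larger = more homogeneous counties).  ``ensure_all_cells``
    forces every county to have all 208 cells populated.
    """

    n_counties: int = 67
    n_per_county: int | tuple[int, ...] = 500
    true_beta: tuple[float, ...] | None = None
    sigma_re: float = 0.3
    poverty_range: tuple[float, float] = (10.0, 40.0)
    county_pop_range: tuple[float, float] = (20_000.0, 800_000.0)
    prevalence_preset: str = "copd"
    concentration: float = 80.0
    ensure_all_cells: bool = False
    seed: int = 0
    age_levels: int = AGE_LEVELS
    sex_levels: int = SEX_LEVELS
    race_levels: int = RACE_LEVELS

    def __post_init__(self) -> None:
        if self.n_counties < 2:
            raise ValueError("n_counties must be >= 2")
        if self.sigma_re < 0:
            raise ValueError("sigma_re must be >= 0")
        if min(self.county_pop_range) <= 0:
            raise ValueError("county populations must be positive")
        ns = self.n_per_county_vector
        if len(ns) != self.n_counties or (ns < 1).any():
            raise ValueError("n_per_county must be >= 1 (scalar or length n_counties)")
        if self.prevalence_preset not in (*PRESET_TARGETS, "custom"):
            raise ValueError(f"unknown preset {self.prevalence_preset!r}")
        if self.prevalence_preset == "custom" and self.true_beta is None:
            raise ValueError("custom preset requires true_beta")

    @property
    def n_per_county_vector(self) -> np.ndarray:
        if np.isscalar(self.n_per_county):
            return np.full(self.n_counties, int(self.n_per_county))
        return np.asarray(self.n_per_county, dtype=int)


@dataclass
class AreaTruth:
    """Exact prevalences implied by the generating parameters."""

    county_ids: list
    county_prevalence: np.ndarray
    state_prevalence: float
    true_beta: np.ndarray
    re: np.ndarray
    sigma_re: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "county_ids": list(self.county_ids),
            "county_prevalence": self.county_prevalence.tolist(),
            "state_prevalence": self.state_prevalence,
            "true_beta": self.true_beta.tolist(),
            "re": self.re.tolist(),
            "sigma_re": self.sigma_re,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AreaTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            county_ids=d["county_ids"],
            county_prevalence=np.asarray(d["county_prevalence"]),
            state_prevalence=float(d["state_prevalence"]),
            true_beta=np.asarray(d["true_beta"]),
            re=np.asarray(d["re"]),
            sigma_re=float(d["sigma_re"]),
        )


@dataclass
class SyntheticWorld:
    """A complete generated study: data tables plus ground truth."""

    census: pd.DataFrame
    covariates: pd.DataFrame
    survey: pd.DataFrame
    truth: AreaTruth
    config: GeneratorConfig
    frame: PoststratFrame = field(repr=False, default=None)


def _base_cell_probs(spec: DesignSpec) -> np.ndarray:
    age = _BASE_AGE[: spec.age_levels] / _BASE_AGE[: spec.age_levels].sum()
    sex = _BASE_SEX / _BASE_SEX.sum()
    race = _BASE_RACE[: spec.race_levels] / _BASE_RACE[: spec.race_levels].sum()
    p = np.einsum("a,s,r->asr", age, sex, race).ravel()
    return p / p.sum()


def _cell_levels(spec: DesignSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    age, sex, race = np.meshgrid(
        np.arange(1, spec.age_levels + 1),
        np.arange(1, spec.sex_levels + 1),
        np.arange(1, spec.race_levels + 1),
        indexing="ij",
    )
    return age.ravel(), sex.ravel(), race.ravel()


def generate_population(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the census post-stratification table and county covariates.

    Cell counts are Dirichlet-multinomial around the base composition and
    scaled to a log-uniform county adult population; the poverty covariate is
    uniform over ``poverty_range``.  Zero-count cells are omitted (so the
    per-county cell count m can be < 208) unless ``ensure_all_cells``.
    """
    spec = DesignSpec(config.age_levels, config.sex_levels, config.race_levels)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])
    base = _base_cell_probs(spec)
    n_cells = base.shape[0]
    age, sex, race = _cell_levels(spec)
    lo, hi = config.county_pop_range
    pops = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_counties)).astype(int)
    records = []
    for j in range(config.n_counties):
        probs = rng.dirichlet(config.concentration * base)
        counts = rng.multinomial(pops[j], probs)
        if config.ensure_all_cells:
            counts = counts + 1
        for k in range(n_cells):
            if counts[k] > 0:
                records.append((j + 1, age[k], sex[k], race[k], counts[k]))
    census = pd.DataFrame(records, columns=["county_id", "age_group", "sex", "race_eth", "population"])
    pov = rng.uniform(*config.poverty_range, config.n_counties)
    covariates = pd.DataFrame({
        "county_id": np.arange(1, config.n_counties + 1),
        "poverty_pct": np.round(pov, 2),
    })
    return census, covariates


def resolve_true_beta(config: GeneratorConfig, frame: PoststratFrame) -> np.ndarray:
    """The generating coefficient vector, with the preset intercept solved.

    For a named preset the slopes are fixed and the intercept is chosen by
    root finding so the post-stratified population prevalence (at re = 0)
    equals the preset target exactly on this census frame.
    """
    if config.prevalence_preset == "custom":
        beta = np.asarray(config.true_beta, dtype=float)
        if beta.shape[0] != frame.spec.n_columns:
            raise ValueError("true_beta length does not match the design")
        return beta
    target = PRESET_TARGETS[config.prevalence_preset]
    slopes = np.asarray(_PRESET_SLOPES[config.prevalence_preset])
    eta_rest = frame.X[:, 1:] @ slopes
    w = frame.counts / frame.counts.sum()

    def marginal(b0: float) -> float:
        return float(w @ expit(b0 + eta_rest)) - target

    b0 = brentq(marginal, -20.0, 20.0)
    return np.concatenate([[b0], slopes])


def generate_survey(
    census: pd.DataFrame,
    covariates: pd.DataFrame,
    true_beta: np.ndarray,
    sigma_re: float,
    n_per_county: np.ndarray | int,
    seed: int,
    frame: PoststratFrame | None = None,
) -> tuple[pd.DataFrame, AreaTruth]:
    """Sample respondents and outcomes from the generating model.

    Respondents are drawn from each county's census cell distribution;
    design weights are inverse sampling fractions N_cell / n_cell; outcomes
    are Bernoulli with probability expit(X_i . beta + re_j).  The returned
    truth holds the exact post-stratified prevalences under (beta, re).
    """
    frame = frame if frame is not None else build_frame(census, covariates)
    J = frame.n_counties
    ns = np.full(J, n_per_county) if np.isscalar(n_per_county) else np.asarray(n_per_county, dtype=int)
    ss = np.random.SeedSequence(seed).spawn(4)
    rng_re = np.random.default_rng(ss[1])
    rng_samp = np.random.default_rng(ss[2])
    rng_out = np.random.default_rng(ss[3])

    re = rng_re.normal(0.0, sigma_re, J)
    true_beta = np.asarray(true_beta, dtype=float)
    county_prev, state_prev = area_prevalence(true_beta, re, frame)
    truth = AreaTruth(
        county_ids=list(frame.county_ids),
        county_prevalence=county_prev,
        state_prevalence=state_prev,
        true_beta=true_beta,
        re=re,
        sigma_re=float(sigma_re),
    )

    cells = census[census["population"] > 0].reset_index(drop=True)
    rows = []
    rid = 0
    for code, cid in enumerate(frame.county_ids):
        sub = cells[cells["county_id"] == cid]
        N = sub["population"].to_numpy(dtype=float)
        if ns[code] > N.sum():
            raise ValueError(f"county {cid}: sample size {ns[code]} exceeds population {int(N.sum())}")
        n_cell = rng_samp.multinomial(ns[code], N / N.sum())
        for (_, cell), nk in zip(sub.iterrows(), n_cell):
            if nk == 0:
                continue
            w = cell["population"] / nk
            for _ in range(nk):
                rid += 1
                rows.append((rid, cid, cell["age_group"], cell["sex"], cell["race_eth"], w))
    survey = pd.DataFrame(rows, columns=["respondent_id", "county_id", "age_group", "sex", "race_eth", "design_weight"])

    cov = covariates.set_index("county_id")["poverty_pct"]
    code = {c: i for i, c in enumerate(frame.county_ids)}
    cidx = survey["county_id"].map(code).to_numpy()
    X = encode_rows(
        survey["age_group"].to_numpy(),
        survey["sex"].to_numpy(),
        survey["race_eth"].to_numpy(),
        survey["county_id"].map(cov).to_numpy(dtype=float),
        frame.spec,
    )
    p = expit(X @ true_beta + re[cidx])
    survey["outcome"] = (rng_out.random(len(survey)) < p).astype(int)
    return survey, truth


def generate_world(config: GeneratorConfig) -> SyntheticWorld:
    """End-to-end generation from one master seed."""
    census, covariates = generate_population(config)
    frame = build_frame(census, covariates)
    beta = resolve_true_beta(config, frame)
    survey, truth = generate_survey(
        census, covariates, beta, config.sigma_re,
        config.n_per_county_vector, config.seed, frame=frame,
    )
    return SyntheticWorld(census=census, covariates=covariates, survey=survey,
                          truth=truth, config=config, frame=frame)


def world_with_seed(config: GeneratorConfig, seed: int) -> SyntheticWorld:
    """Same study conditions, different random world."""
    return generate_world(replace(config, seed=seed))
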