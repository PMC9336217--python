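"""Fixed-effects design matrix for the county-prevalence model.

The model regresses a binary outcome on individual demographics (age group,
sex, race/ethnicity) and one county-level covariate (percent of adults below
150% of the poverty line).  Categorical predictors use reference-cell dummy
coding: age group 1 (18-24 years), male, and non-Hispanic white are the
reference levels, so the design has

    1 intercept + 12 age + 1 sex + 7 race/ethnicity + 1 poverty = 22 columns.

The same encoder serves survey respondents and census post-stratification
cells, which guarantees that the post-stratified predictions use exactly the
coding the model was fit with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_LEVELS = 13
SEX_LEVELS = 2
RACE_LEVELS = 8


@dataclass(frozen=True)
class DesignSpec:
    """Column layout of the fixed-effects design matrix.

    Reference levels (age group 1, sex 1 = male, race/ethnicity 1 =
    non-Hispanic white) carry no dummy column; the county poverty percentage
    enters as a single continuous column on the 0-100 scale.
    """

    age_levels: int = AGE_LEVELS
    sex_levels: int = SEX_LEVELS
    race_levels: int = RACE_LEVELS
    column_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.column_names:
            names = ["intercept"]
            names += [f"age_{a}" for a in range(2, self.age_levels + 1)]
            names += ["sex_2"]
            names += [f"race_{r}" for r in range(2, self.race_levels + 1)]
            names += ["poverty"]
            object.__setattr__(self, "column_names", tuple(names))

    @property
    def n_columns(self) -> int:
        return 1 + (self.age_levels - 1) + (self.sex_levels - 1) + (self.race_levels - 1) + 1


def encode_rows(
    age: np.ndarray,
    sex: np.ndarray,
    race: np.ndarray,
    poverty: np.ndarray,
    spec: DesignSpec | None = None,
) -> np.ndarray:
    """Encode demographic levels into design-matrix rows.

    ``age``, ``sex`` and ``race`` are 1-based level codes; ``poverty`` is the
    county covariate already joined to each row.  Raises ``ValueError`` naming
    the offending level when a code falls outside the coding scheme.
    """
    spec = spec or DesignSpec()
    age = np.asarray(age, dtype=int)
    sex = np.asarray(sex, dtype=int)
    race = np.asarray(race, dtype=int)
    poverty = np.asarray(poverty, dtype=float)
    n = age.shape[0]

    for name, vals, levels in (
        ("age_group", age, spec.age_levels),
        ("sex", sex, spec.sex_levels),
        ("race_eth", race, spec.race_levels),
    ):
        bad = (vals < 1) | (vals > levels)
        if bad.any():
            raise ValueError(
                f"unseen {name} level(s) {sorted(set(vals[bad].tolist()))}; "
                f"valid levels are 1..{levels}"
            )

    X = np.zeros((n, spec.n_columns))
    X[:, 0] = 1.0
    rows = np.arange(n)
    # dummy blocks: level 1 is the reference cell (all zeros)
    off = 1
    m = age > 1
    X[rows[m], off + age[m] - 2] = 1.0
    off += spec.age_levels - 1
    m = sex > 1
    X[rows[m], off + sex[m] - 2] = 1.0
    off += spec.sex_levels - 1
    m = race > 1
    X[rows[m], off + race[m] - 2] = 1.0
    X[:, -1] = poverty
    return X


def build_design(
    survey: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: DesignSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Build (X, y, county_index, county_ids) from survey microdata.

    ``survey`` needs columns county_id, age_group, sex, race_eth, outcome;
    ``covariates`` needs county_id and poverty_pct.  Counties are indexed in
    sorted county_id order; ``county_index`` maps each respondent to that
    order.  Every respondent's county must have a covariate row.
    """
    spec = spec or DesignSpec()
    cov = covariates.set_index("county_id")["poverty_pct"]
    missing = set(survey["county_id"]) - set(cov.index)
    if missing:
        raise ValueError(f"counties without covariate rows: {sorted(missing)}")
    county_ids = sorted(survey["county_id"].unique().tolist())
    code = {c: i for i, c in enumerate(county_ids)}
    county_index = survey["county_id"].map(code).to_numpy()
    poverty = survey["county_id"].map(cov).to_numpy(dtype=float)
    X = encode_rows(
        survey["age_group"].to_numpy(),
        survey["sex"].to_numpy(),
        survey["race_eth"].to_numpy(),
        poverty,
        spec,
    )
    y = survey["outcome"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    return X, y, county_index, county_ids
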