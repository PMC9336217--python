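"""Design-based direct survey estimates (the model-free comparator).

The direct estimator is the weighted prevalence sum(w_i y_i) / sum(w_i)
per area, with a 95% normal interval using the standard linearisation
variance of a weighted ratio,

    var = sum w_i^2 (y_i - p_hat)^2 / (sum w_i)^2,

truncated to [0, 1].  Stratification and clustering beyond county are not
modelled; weights are whatever the survey supplies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .drawset import STATE_ID


def _one_area(w: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    tot = w.sum()
    if tot <= 0:
        raise ValueError("area with zero total weight")
    p = float(w @ y / tot)
    var = float(np.sum((w * (y - p)) ** 2) / tot**2)
    half = 1.96 * np.sqrt(var)
    return p, max(0.0, p - half), min(1.0, p + half)


def direct_estimate(survey: pd.DataFrame) -> pd.DataFrame:
    """Weighted prevalence and 95% CI per county and for the whole state."""
    w_all = survey["design_weight"].to_numpy(dtype=float)
    if (w_all <= 0).any():
        raise ValueError("design weights must be positive")
    y_all = survey["outcome"].to_numpy(dtype=float)
    rows = []
    for cid, sub in survey.groupby("county_id", sort=True):
        p, lo, hi = _one_area(sub["design_weight"].to_numpy(dtype=float),
                              sub["outcome"].to_numpy(dtype=float))
        rows.append((str(cid), "direct", p, lo, hi, len(sub)))
    p, lo, hi = _one_area(w_all, y_all)
    rows.append((STATE_ID, "direct", p, lo, hi, len(survey)))
    return pd.DataFrame(rows, columns=["area_id", "method", "mean", "lo95", "hi95", "n_draws"])
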