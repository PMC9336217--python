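"""Draw matrices and the percentile-interval operator shared by all methods.

Every interval method (posterior sampling, parameter simulation, both
bootstraps) ends the same way: a matrix of simulated prevalences per area
from which an equal-tailed 95% interval is read off.  The percentile
convention is the order-statistic one: with B sorted draws the interval is
(v_(ceil(a/2*B)), v_(ceil((1-a/2)*B))), so at B = 1000 and alpha = 0.05 the
endpoints are the 25th and 975th values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STATE_ID = "state"


def percentile_interval(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Equal-tailed empirical interval by order statistics.

    Requires at least ceil(1/(alpha/2)) values so the tail order statistics
    are defined (>= 40 at the default alpha).
    """
    v = np.sort(np.asarray(values, dtype=float))
    B = v.shape[0]
    need = int(np.ceil(1.0 / (alpha / 2.0)))
    if B < need:
        raise ValueError(f"need at least {need} values for alpha={alpha}, got {B}")
    lo_k = int(np.ceil(alpha / 2.0 * B))
    hi_k = int(np.ceil((1.0 - alpha / 2.0) * B))
    return float(v[lo_k - 1]), float(v[hi_k - 1])


@dataclass
class DrawSet:
    """R draws of prevalence for each area (counties plus the state)."""

    method: str
    values: np.ndarray  # (R, J + 1); last column is the state
    area_ids: list  # county ids then STATE_ID
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.area_ids):
            raise ValueError("values width must match area_ids")
        if not ((self.values > 0.0) & (self.values < 1.0)).all():
            raise ValueError("prevalence draws must lie strictly inside (0, 1)")

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=[str(a) for a in self.area_ids])

    def to_estimates(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-area mean and equal-tailed interval as an AreaEstimate table."""
        rows = []
        for k, area in enumerate(self.area_ids):
            col = self.values[:, k]
            lo, hi = percentile_interval(col, alpha)
            rows.append((str(area), self.method, float(col.mean()), lo, hi, self.n_draws))
        return pd.DataFrame(rows, columns=["area_id", "method", "mean", "lo95", "hi95", "n_draws"])


def area_ids_with_state(county_ids: list) -> list:
    return [*county_ids, STATE_ID]
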