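"""Linear regression of labeling index on follicle diameter.

Beyond ~170 um the granulosa labeling index declines roughly linearly with
diameter.  Two subsets characterise the decline: the full non-atretic
population ("median" growth), and the fast-growing fraction — the top 20% of
follicles by LI within each 50-um diameter bin between 170 and 350 um, plus
all follicles above 350 um.  The fitted slope feeds the growth model's
proliferation-decline term.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["LiDeclineModel", "LiDeclineResults", "LiRegression", "select_fast_top20"]

SubsetRule = Literal["median_all", "fast_top20"]


@dataclasses.dataclass(frozen=True)
class LiRegression:
    """Portable fitted line: predicted LI = intercept + slope * diameter.

    ``slope`` is stored signed (negative for a decline); predictions are
    clamped to [0, 1] on use.
    """

    intercept: float
    slope: float
    subset_rule: SubsetRule
    diameter_range: tuple[float, float]
    n_obs: int

    def predict(self, diameter: float | np.ndarray) -> np.ndarray:
        return np.clip(self.intercept + self.slope * np.asarray(diameter), 0.0, 1.0)

    @property
    def decline_slope(self) -> float:
        """Non-negative decline rate usable as ``li_decline_slope``."""
        return max(0.0, -self.slope)


def select_fast_top20(
    records: pd.DataFrame,
    diameter_range: tuple[float, float] = (170.0, 350.0),
    bin_width: float = 50.0,
) -> pd.DataFrame:
    """Top 20% of follicles by LI per 50-um diameter bin, plus all above range.

    Bins are ``[lo, lo+50), ...`` up to the upper range bound (a final
    partial bin is kept); the per-bin count is ``ceil(0.2 * n)``; ties are
    broken toward the smaller diameter.  Follicles larger than the upper
    bound are all retained.
    """
    lo, hi = diameter_range
    d = records["pseudodiameter_um"].to_numpy()
    above = records[d > hi]
    parts = [above]
    edges = np.arange(lo, hi, bin_width)
    for left in edges:
        right = min(left + bin_width, hi)
        in_bin = records[(d >= left) & (d < right)]
        if len(in_bin) == 0:
            raise ValueError(f"empty diameter bin [{left}, {right})")
        k = math.ceil(0.2 * len(in_bin))
        top = in_bin.sort_values(
            ["li", "pseudodiameter_um"], ascending=[False, True]
        ).head(k)
        parts.append(top)
    return pd.concat(parts).sort_index()


class LiDeclineModel:
    """OLS model of labeling index versus follicle diameter.

    Parameters
    ----------
    records : DataFrame
        One row per follicle with at least ``pseudodiameter_um`` and ``li``
        columns; rows should already be restricted to included, non-atretic
        follicles (use :meth:`from_records` to apply those filters from a
        full follicle table).
    subset_rule : {"median_all", "fast_top20"}
        Whether to fit all follicles in range or only the fast-growing
        per-bin top 20% (plus everything above the range).
    diameter_range : (low, high)
        Diameter window (um) the regression is fitted over; follicles above
        ``high`` are always included (the preovulatory class has no upper
        bound).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        subset_rule: SubsetRule = "median_all",
        diameter_range: tuple[float, float] = (170.0, 350.0),
    ) -> None:
        if subset_rule not in ("median_all", "fast_top20"):
            raise ValueError(f"unknown subset rule {subset_rule!r}")
        required = {"pseudodiameter_um", "li"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        lo, hi = diameter_range
        in_scope = records[records["pseudodiameter_um"] >= lo]
        if subset_rule == "fast_top20":
            self.subset = select_fast_top20(in_scope, diameter_range)
        else:
            self.subset = in_scope
        if len(self.subset) < 3:
            raise ValueError("regression requires at least 3 follicles")
        self.subset_rule: SubsetRule = subset_rule
        self.diameter_range = diameter_range

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        subset_rule: SubsetRule = "median_all",
        diameter_range: tuple[float, float] = (170.0, 350.0),
    ) -> "LiDeclineModel":
        """Build from a full follicle table, dropping excluded/atretic rows."""
        df = records
        if "included" in df.columns:
            df = df[df["included"].astype(bool)]
        if "atretic" in df.columns:
            df = df[~df["atretic"].astype(bool)]
        return cls(df, subset_rule=subset_rule, diameter_range=diameter_range)

    def fit(self) -> "LiDeclineResults":
        x = sm.add_constant(self.subset["pseudodiameter_um"].to_numpy())
        ols = sm.OLS(self.subset["li"].to_numpy(), x).fit()
        return LiDeclineResults(self, ols)


class LiDeclineResults:
    """Wraps the OLS fit and exposes the portable :class:`LiRegression`."""

    def __init__(self, model: LiDeclineModel, ols_results) -> None:
        self.model = model
        self._ols = ols_results
        self.intercept = float(ols_results.params[0])
        self.slope = float(ols_results.params[1])
        self.bse = np.asarray(ols_results.bse, dtype=float)
        self.rsquared = float(ols_results.rsquared)
        self.nobs = int(ols_results.nobs)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        return np.asarray(self._ols.conf_int(alpha))

    def as_regression(self) -> LiRegression:
        return LiRegression(
            intercept=self.intercept,
            slope=self.slope,
            subset_rule=self.model.subset_rule,
            diameter_range=self.model.diameter_range,
            n_obs=self.nobs,
        )

    def predict(self, diameter: float | np.ndarray) -> np.ndarray:
        return self.as_regression().predict(diameter)

    def summary(self) -> str:
        head = (
            f"LI-vs-diameter regression ({self.model.subset_rule}, "
            f"range {self.model.diameter_range[0]:g}-"
            f"{self.model.diameter_range[1]:g} um)\n"
        )
        return head + str(self._ols.summary())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<LiDeclineResults slope={self.slope:.5g} "
            f"intercept={self.intercept:.4g} n={self.nobs}>"
        )
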