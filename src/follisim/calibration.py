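"""Calibration of the growth model's adjustment factor against observed data.

The raw labeling index overestimates effective daily proliferation (not every
labelled cell completes division within the iteration, and label uptake
overshoots the realised growth), so the model damps the proliferation term by
a scalar adjustment factor.  Here that factor is estimated by least squares:
simulated diameters are matched to an observed sequence of (day, mean
diameter) pairs — in the source study, the mean diameter of the five largest
follicles at successive cycle stages (334, 388, 441 um) — and the residual
sum of squares is minimised over the adjustment factor by bounded 1-D search.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.optimize import minimize_scalar

from .params import GrowthModelParams

__all__ = ["GrowthCalibrationModel", "GrowthCalibrationResults"]


class GrowthCalibrationModel:
    """Least-squares model for the proliferation adjustment factor.

    Parameters
    ----------
    observed : iterable of (day, diameter)
        At least two observations with strictly increasing days and
        diameters.  Day 0 sets the starting diameter of the simulated
        follicle; if no day-0 observation is present the earliest
        observation is used as the start and is fitted exactly.
    li_initial : float
        Labeling index of the follicle at the first observation.
    params : GrowthModelParams, optional
        All constants except the adjustment factor, which is the free
        parameter (its value in ``params`` is ignored).
    bounds : (low, high)
        Search interval for the adjustment factor.

    Examples
    --------
    >>> from follisim.growth import simulate_growth
    >>> traj = simulate_growth(334.0, 0.303, 3)
    >>> obs = list(zip(traj.days.tolist(), traj.diameters.tolist()))
    >>> res = GrowthCalibrationModel(obs, 0.303).fit()
    >>> round(res.adjustment_factor, 3)
    0.795
    """

    def __init__(
        self,
        observed: Iterable[tuple[int, float]],
        li_initial: float,
        params: GrowthModelParams | None = None,
        bounds: tuple[float, float] = (1e-6, 1.5),
    ) -> None:
        obs = sorted((int(d), float(diam)) for d, diam in observed)
        if len(obs) < 2:
            raise ValueError("calibration requires at least two observations")
        days = [d for d, _ in obs]
        diams = [x for _, x in obs]
        if len(set(days)) != len(days):
            raise ValueError("observation days must be distinct")
        if any(b <= a for a, b in zip(diams, diams[1:])):
            raise ValueError("observed diameters must increase with day")
        if not 0 <= li_initial <= 1:
            raise ValueError("li_initial must lie in [0, 1]")
        if not 0 < bounds[0] < bounds[1]:
            raise ValueError("invalid bounds")
        self.observed_days = np.array(days)
        self.observed_diameters = np.array(diams)
        self.li_initial = float(li_initial)
        self.params = params or GrowthModelParams()
        self.bounds = bounds

    def _predict(self, adjustment: float) -> np.ndarray:
        """Simulated diameters at the observed days for a candidate factor.

        The forward recursion is written out explicitly (rather than through
        ``simulate_growth``) so candidate factors above 1 remain inside the
        search space.
        """
        p = self.params
        d0 = float(self.observed_diameters[0])
        day0 = int(self.observed_days[0])
        n = p.volume_coefficient * d0**p.volume_exponent / p.granulosa_cell_volume
        diam = d0
        out = {day0: d0}
        for day in range(day0 + 1, int(self.observed_days[-1]) + 1):
            declined = max(
                0.0, self.li_initial - p.li_decline_slope * (diam - d0)
            )
            eff = min(1.0, adjustment * declined)
            n *= 1.0 + eff
            diam = (n * p.granulosa_cell_volume / p.volume_coefficient) ** (
                1.0 / p.volume_exponent
            )
            out[day] = diam
        return np.array([out[d] for d in self.observed_days])

    def _sse(self, adjustment: float) -> float:
        resid = self._predict(adjustment) - self.observed_diameters
        return float(resid @ resid)

    def fit(self) -> "GrowthCalibrationResults":
        """Bounded scalar minimisation of the residual sum of squares."""
        opt = minimize_scalar(
            self._sse, bounds=self.bounds, method="bounded",
            options={"xatol": 1e-10},
        )
        ahat = float(opt.x)
        fitted = self._predict(ahat)
        resid = self.observed_diameters - fitted
        # curvature-based standard error: sse(a) ~ sse(ahat) + 0.5 h (a-ahat)^2,
        # se = sqrt(2 * sigma^2 / h) with sigma^2 from the residuals
        dof = max(len(resid) - 1, 1)
        sigma2 = float(resid @ resid) / dof
        eps = 1e-4
        h = (self._sse(ahat + eps) - 2 * self._sse(ahat) + self._sse(ahat - eps)) / eps**2
        se = float(np.sqrt(2 * sigma2 / h)) if h > 0 else np.nan
        return GrowthCalibrationResults(
            model=self,
            adjustment_factor=ahat,
            sse=float(opt.fun),
            fitted_diameters=fitted,
            residuals=resid,
            bse=se,
            converged=bool(opt.success),
        )


class GrowthCalibrationResults:
    """Fit results for :class:`GrowthCalibrationModel`."""

    def __init__(
        self,
        model: GrowthCalibrationModel,
        adjustment_factor: float,
        sse: float,
        fitted_diameters: np.ndarray,
        residuals: np.ndarray,
        bse: float,
        converged: bool,
    ) -> None:
        self.model = model
        self.adjustment_factor = adjustment_factor
        self.sse = sse
        self.fitted_diameters = fitted_diameters
        self.residuals = residuals
        self.bse = bse
        self.converged = converged

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2)))

    def params_with_adjustment(self) -> GrowthModelParams:
        """Base parameters with the fitted adjustment factor substituted.

        Raises if the fitted factor falls outside the (0, 1] range the
        growth model accepts.
        """
        return self.model.params.replace(adjustment_factor=self.adjustment_factor)

    def summary(self) -> str:
        lines = [
            "Growth adjustment-factor calibration",
            "=" * 44,
            f"n observations        {len(self.model.observed_days):>10d}",
            f"adjustment factor     {self.adjustment_factor:>10.4f}",
            f"std err (curvature)   {self.bse:>10.4f}",
            f"residual SSE (um^2)   {self.sse:>10.4g}",
            f"RMSE (um)             {self.rmse:>10.4g}",
            f"converged             {str(self.converged):>10s}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<GrowthCalibrationResults adjustment={self.adjustment_factor:.4f} "
            f"rmse={self.rmse:.3g}>"
        )
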