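"""Iterative granulosa-cell growth model of antral follicle expansion.

The model converts between follicle diameter and mural granulosa cell number
through the power-law mural volume (``V_M = a D**b``) and the fixed volume of
one granulosa cell, then grows the cell population day by day:

    N_i = N_{i-1} * (1 + LI_eff(D_{i-1}))
    LI_eff(D) = adjustment * clip(LI_0 - slope * (D - D_0), 0, 1)

where ``LI_0`` is the labeling index measured at day 0, ``slope`` the linear
decline of proliferation with diameter gained, and ``adjustment`` the
calibrated damping factor.  Diameters are um, volumes um^3, labeling indices
fractions in [0, 1], iterations 24 h.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .params import GrowthModelParams

__all__ = [
    "FollicleState",
    "GrowthTrajectory",
    "mural_volume",
    "cell_count_from_diameter",
    "diameter_from_cell_count",
    "effective_li",
    "grow_one_day",
    "simulate_growth",
    "days_to_diameter",
    "generate_table1",
    "calibrate_adjustment",
    "UNREACHED",
]

#: Sentinel returned by :func:`days_to_diameter` when the target diameter is
#: not reached within ``max_days``.
UNREACHED = "unreached"


@dataclasses.dataclass(frozen=True)
class FollicleState:
    """Snapshot of one follicle at an integer day of the simulation.

    ``diameter`` (um) and ``cell_count`` (mural granulosa cells, real-valued
    during iteration) are mutually consistent under the volume model;
    ``li_initial`` is the day-0 labeling index carried along the trajectory.
    """

    diameter: float
    cell_count: float
    li_initial: float
    day: int = 0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.cell_count <= 0:
            raise ValueError("diameter and cell_count must be positive")
        if not 0 <= self.li_initial <= 1:
            raise ValueError("li_initial must lie in [0, 1]")
        if self.day < 0:
            raise ValueError("day must be >= 0")

    @classmethod
    def from_diameter(
        cls,
        diameter: float,
        li_initial: float,
        params: GrowthModelParams,
        day: int = 0,
    ) -> "FollicleState":
        return cls(
            diameter=diameter,
            cell_count=cell_count_from_diameter(diameter, params),
            li_initial=li_initial,
            day=day,
        )


@dataclasses.dataclass(frozen=True)
class GrowthTrajectory:
    """Ordered daily states of one simulated follicle.

    ``effective_li_per_day[i]`` is the labeling index actually applied in the
    step from day ``i`` to day ``i+1`` (length ``len(states) - 1``).
    """

    states: tuple[FollicleState, ...]
    effective_li_per_day: tuple[float, ...]

    def __post_init__(self) -> None:
        days = [s.day for s in self.states]
        if days != list(range(days[0], days[0] + len(days))):
            raise ValueError("trajectory days must increase by 1")
        if len(self.effective_li_per_day) != len(self.states) - 1:
            raise ValueError("one effective LI per growth step required")

    @property
    def diameters(self) -> np.ndarray:
        return np.array([s.diameter for s in self.states])

    @property
    def cell_counts(self) -> np.ndarray:
        return np.array([s.cell_count for s in self.states])

    @property
    def days(self) -> np.ndarray:
        return np.array([s.day for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        eff = list(self.effective_li_per_day) + [np.nan]
        return pd.DataFrame(
            {
                "day": self.days,
                "diameter_um": self.diameters,
                "cell_count": self.cell_counts,
                "effective_li": eff,
            }
        )


def mural_volume(diameter: float, params: GrowthModelParams | None = None) -> float:
    """Mural granulosa layer volume (um^3) at a given follicle diameter (um).

    Power law ``V_M = a * D**b``; strictly increasing in diameter.
    """
    params = params or GrowthModelParams()
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    return params.volume_coefficient * diameter**params.volume_exponent


def cell_count_from_diameter(
    diameter: float, params: GrowthModelParams | None = None
) -> float:
    """Number of granulosa cells filling the mural layer at ``diameter`` um."""
    params = params or GrowthModelParams()
    return mural_volume(diameter, params) / params.granulosa_cell_volume


def diameter_from_cell_count(
    cell_count: float, params: GrowthModelParams | None = None
) -> float:
    """Follicle diameter (um) whose mural layer holds ``cell_count`` cells.

    Closed-form inverse ``D = (N * V_G / a) ** (1/b)``.
    """
    params = params or GrowthModelParams()
    if cell_count < 0:
        raise ValueError("cell_count must be non-negative")
    return (
        cell_count * params.granulosa_cell_volume / params.volume_coefficient
    ) ** (1.0 / params.volume_exponent)


def effective_li(
    li_initial: float,
    diameter_now: float,
    diameter_start: float,
    params: GrowthModelParams | None = None,
) -> float:
    """Labeling index applied at the current iteration.

    The day-0 labeling index is reduced by ``slope`` per um of diameter
    gained since the start, floored at zero (a proliferating fraction cannot
    be negative), then damped by the adjustment factor.  At the first
    iteration (no diameter gain) this reduces to ``adjustment * li_initial``.
    """
    params = params or GrowthModelParams()
    if not 0 <= li_initial <= 1:
        raise ValueError("li_initial must lie in [0, 1]")
    if diameter_start <= 0 or diameter_now < diameter_start:
        raise ValueError("require diameter_now >= diameter_start > 0")
    declined = li_initial - params.li_decline_slope * (diameter_now - diameter_start)
    return float(np.clip(params.adjustment_factor * max(0.0, declined), 0.0, 1.0))


def grow_one_day(
    state: FollicleState,
    start: FollicleState,
    params: GrowthModelParams | None = None,
) -> FollicleState:
    """Advance one follicle by one 24-h iteration.

    Cells divide at the effective labeling index evaluated at the current
    diameter; the enlarged cell population is converted back to a diameter.
    Cell count never decreases (the effective LI is non-negative).
    """
    params = params or GrowthModelParams()
    if start.day != 0:
        raise ValueError("start state must be at day 0")
    li = effective_li(state.li_initial, state.diameter, start.diameter, params)
    new_count = state.cell_count * (1.0 + li)
    return FollicleState(
        diameter=diameter_from_cell_count(new_count, params),
        cell_count=new_count,
        li_initial=state.li_initial,
        day=state.day + 1,
    )


def simulate_growth(
    diameter_start: float,
    li_initial: float,
    days: int,
    params: GrowthModelParams | None = None,
) -> GrowthTrajectory:
    """Iterate the growth model for ``days`` consecutive 24-h steps.

    Returns a trajectory of ``days + 1`` states (day 0 included).
    """
    params = params or GrowthModelParams()
    if days < 0:
        raise ValueError("days must be >= 0")
    start = FollicleState.from_diameter(diameter_start, li_initial, params)
    states = [start]
    applied: list[float] = []
    current = start
    for _ in range(days):
        applied.append(
            effective_li(current.li_initial, current.diameter, start.diameter, params)
        )
        current = grow_one_day(current, start, params)
        states.append(current)
    return GrowthTrajectory(states=tuple(states), effective_li_per_day=tuple(applied))


def days_to_diameter(
    diameter_start: float,
    li_initial: float,
    diameter_target: float,
    params: GrowthModelParams | None = None,
    max_days: int = 60,
) -> int | str:
    """Smallest day index at which the trajectory reaches ``diameter_target``.

    Returns :data:`UNREACHED` if the target is not attained within
    ``max_days`` iterations.  Monotone: larger ``li_initial`` or
    ``diameter_start`` never increases the answer.
    """
    params = params or GrowthModelParams()
    if diameter_target <= diameter_start:
        raise ValueError("diameter_target must exceed diameter_start")
    if max_days < 1:
        raise ValueError("max_days must be >= 1")
    start = FollicleState.from_diameter(diameter_start, li_initial, params)
    current = start
    for day in range(1, max_days + 1):
        current = grow_one_day(current, start, params)
        if current.diameter >= diameter_target:
            return day
    return UNREACHED


def generate_table1(
    diameters: Sequence[float],
    proliferation_rates: Sequence[float],
    params: GrowthModelParams | None = None,
) -> pd.DataFrame:
    """Mural volume, cell count and daily cell increase per follicle size.

    One row per (diameter, proliferation rate) pair: the mural volume from
    the power law, the cell count from the single-cell volume, and the
    expected 24-h cell-number increase ``count * rate``.
    """
    params = params or GrowthModelParams()
    if len(diameters) != len(proliferation_rates):
        raise ValueError("diameters and proliferation_rates must have equal length")
    rates = np.asarray(proliferation_rates, dtype=float)
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("proliferation rates must be fractions in [0, 1]")
    vols = np.array([mural_volume(d, params) for d in diameters])
    counts = vols / params.granulosa_cell_volume
    return pd.DataFrame(
        {
            "diameter_um": np.asarray(diameters, dtype=float),
            "mural_volume_um3": vols,
            "cell_count": counts,
            "proliferation_rate": rates,
            "cell_increase": counts * rates,
        }
    )


def calibrate_adjustment(
    observed: Iterable[tuple[int, float]],
    li_initial: float,
    params: GrowthModelParams | None = None,
    bounds: tuple[float, float] = (1e-6, 1.5),
) -> float:
    """Least-squares estimate of the adjustment factor from observed growth.

    Thin functional wrapper over
    :class:`follisim.calibration.GrowthCalibrationModel`; returns only the
    point estimate.
    """
    from .calibration import GrowthCalibrationModel

    model = GrowthCalibrationModel(observed, li_initial, params=params, bounds=bounds)
    return model.fit().adjustment_factor


def _round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 maps to 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
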