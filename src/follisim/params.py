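"""Model parameters and follicle stage definitions.

The growth model treats the mural granulosa layer as the engine of antral
follicle expansion: its volume scales with follicle diameter as a power law
``V_M = a * D**b`` (empirically a = 0.18, b = 3.05 for the mouse), and the
layer is filled by granulosa cells of fixed volume (132.6 um^3).  Daily cell
division, at a rate set by the BrdU labeling index, inflates the mural volume
and hence the diameter.  Because proliferation slows as follicles mature, the
applied labeling index declines linearly with the diameter gained since the
start of the simulation, and the whole proliferation term is damped by a
calibrated adjustment factor (0.795 by default).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "GrowthModelParams",
    "StageThresholds",
    "DEFAULT_LI_DECLINE_SLOPE",
    "DEFAULT_LI_INTERCEPT",
    "load_params",
]

#: Linear decline of labeling index with diameter (fraction per um), the
#: exact line through the mean proliferation-rate column of the reference
#: table (49% at 100 um down to 21% at 450 um).
DEFAULT_LI_DECLINE_SLOPE = 0.0008
#: Intercept of the same line at D = 0 (LI fraction).
DEFAULT_LI_INTERCEPT = 0.57


@dataclasses.dataclass(frozen=True)
class GrowthModelParams:
    """Constants of the iterative granulosa-cell growth model.

    Parameters
    ----------
    volume_coefficient : float
        Coefficient ``a`` of the mural-volume power law (dimensionless,
        default 0.18).
    volume_exponent : float
        Exponent ``b`` of the power law (default 3.05; must exceed 1).
    granulosa_cell_volume : float
        Volume of a single granulosa cell in um^3 (default 132.6).
    adjustment_factor : float
        Multiplicative damping of the effective labeling index, in (0, 1];
        default 0.795, the value calibrated against observed growth of the
        five largest follicles across the estrous cycle.
    li_decline_slope : float
        Decline of the labeling index per um of diameter gained since day 0
        (>= 0; default 0.0008).
    iteration_interval_h : float
        Length of one iteration in hours.  Fixed at 24 because ovulation can
        occur only once per day; exposed for completeness.
    """

    volume_coefficient: float = 0.18
    volume_exponent: float = 3.05
    granulosa_cell_volume: float = 132.6
    adjustment_factor: float = 0.795
    li_decline_slope: float = DEFAULT_LI_DECLINE_SLOPE
    iteration_interval_h: float = 24.0

    def __post_init__(self) -> None:
        if self.volume_coefficient <= 0:
            raise ValueError("volume_coefficient must be positive")
        if self.volume_exponent <= 1:
            raise ValueError("volume_exponent must exceed 1")
        if self.granulosa_cell_volume <= 0:
            raise ValueError("granulosa_cell_volume must be positive")
        if not 0 < self.adjustment_factor <= 1:
            raise ValueError("adjustment_factor must lie in (0, 1]")
        if self.li_decline_slope < 0:
            raise ValueError("li_decline_slope must be non-negative")
        if self.iteration_interval_h <= 0:
            raise ValueError("iteration_interval_h must be positive")

    def replace(self, **changes: Any) -> "GrowthModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class StageThresholds:
    """Diameter boundaries (um) of the antral follicle stages.

    Intervals are contiguous and half-open, ``[lower, upper)``; the
    preovulatory class is ``diameter > preovulatory_min`` (strict, matching
    the ">350 um" convention).  Diameters below ``preantral_min`` are labelled
    ``sub-threshold``.
    """

    preantral_min: float = 80.0
    fsh_sensitive_min: float = 130.0
    fsh_dependent_min: float = 170.0
    preovulatory_min: float = 350.0

    def __post_init__(self) -> None:
        bounds = (
            self.preantral_min,
            self.fsh_sensitive_min,
            self.fsh_dependent_min,
            self.preovulatory_min,
        )
        if any(b <= 0 for b in bounds) or any(
            a >= b for a, b in zip(bounds, bounds[1:])
        ):
            raise ValueError("stage thresholds must be positive and increasing")


def load_params(source: str | Path | Mapping[str, Any]) -> GrowthModelParams:
    """Build :class:`GrowthModelParams` from a YAML/JSON file or a mapping.

    Keys mirror the dataclass field names; missing keys fall back to the
    defaults.  Unknown keys raise ``ValueError`` so configuration typos do
    not pass silently.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    else:
        data = dict(source)
    if data is None:
        data = {}
    known = {f.name for f in dataclasses.fields(GrowthModelParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return GrowthModelParams(**data)
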