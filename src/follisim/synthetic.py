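"""Synthetic follicle populations, section stacks and label masks.

Every input the analysis pipeline consumes can be generated here with known
ground truth, emulating the study conditions: the four-phase labeling-index
trajectory (slow preantral growth with LIs rarely above 30%, a proliferative
spurt between 130 and 170 um, then a linear decline), between-follicle LI
heterogeneity at fixed diameter, stage- and size-dependent atresia that
preferentially removes slow-growing follicles, 2-h and 48-h pulse-chase
designs, serial-section stacks of spherical follicles, and class-coded
segmentation masks of a mural granulosa shell.

All generators are pure functions of (config, seed): identical inputs give
identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal

import numpy as np
import pandas as pd

from .growth import FollicleState, grow_one_day
from .histology import ATRESIA_CRITERIA, CLASS_CODES, RegionOfInterest, SectionSeries
from .params import (
    DEFAULT_LI_DECLINE_SLOPE,
    DEFAULT_LI_INTERCEPT,
    GrowthModelParams,
    StageThresholds,
)

__all__ = [
    "AtresiaHazard",
    "PopulationConfig",
    "SyntheticHistologyConfig",
    "mean_li_at_diameter",
    "sample_population",
    "simulate_pulse_chase",
    "render_section_stack",
    "render_mask",
]

STAGES = ("preantral", "fsh_sensitive", "fsh_dependent", "preovulatory")
CYCLE_STAGES = ("estrus", "metestrus", "diestrus", "proestrus")


@dataclasses.dataclass(frozen=True)
class AtresiaHazard:
    """Daily atresia probability, logistic in (1 - LI percentile).

    Slow-growing follicles (low LI percentile within the at-risk set) face
    the highest hazard, consistent with atretic follicles carrying labeling
    indices in the low range.  The hazard applies only at and above the
    onset diameter (the beginning of FSH dependence) and is scaled per
    estrous-cycle stage (low at estrus, when FSH is unsuppressed).  The
    default base rate and steepness are set so that a majority of
    FSH-dependent follicles turn atretic over a two-day chase ending at
    diestrus, matching the described histology of that stage.
    """

    base_rate: float = 0.6
    steepness: float = 8.0
    onset_diameter: float = 170.0
    stage_multipliers: tuple[tuple[str, float], ...] = (
        ("estrus", 0.3),
        ("metestrus", 1.0),
        ("diestrus", 1.2),
        ("proestrus", 1.0),
    )

    def __post_init__(self) -> None:
        if not 0 <= self.base_rate <= 1:
            raise ValueError("base_rate must lie in [0, 1]")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def multiplier(self, cycle_stage: str) -> float:
        table = dict(self.stage_multipliers)
        if cycle_stage not in table:
            raise ValueError(f"unknown cycle stage {cycle_stage!r}")
        return table[cycle_stage]

    def daily_probability(
        self,
        li: np.ndarray,
        diameter: np.ndarray,
        cycle_stage: str = "diestrus",
    ) -> np.ndarray:
        """Per-follicle daily atresia probability.

        LI percentiles are computed within the supplied at-risk set; the
        logistic is centred at the median percentile.
        """
        li = np.asarray(li, dtype=float)
        diameter = np.asarray(diameter, dtype=float)
        n = len(li)
        if n == 0:
            return np.zeros(0)
        pct = (pd.Series(li).rank(method="average").to_numpy() - 0.5) / n
        logistic = 1.0 / (1.0 + np.exp(-self.steepness * ((1.0 - pct) - 0.5)))
        p = self.base_rate * self.multiplier(cycle_stage) * logistic
        p = np.where(diameter >= self.onset_diameter, p, 0.0)
        return np.clip(p, 0.0, 1.0)


@dataclasses.dataclass(frozen=True)
class PopulationConfig:
    """Generator settings for a synthetic follicle population.

    The LI-vs-diameter mean trajectory is piecewise linear with knots at the
    stage boundaries 130 and 170 um: flat at ``li_preantral_mean`` through
    the preantral phase, rising through the spurt, then declining as
    ``li_intercept + (-li_decline_slope) * D``.  Between-follicle spread at
    fixed diameter is ``li_heterogeneity_sd``; the recorded (measured) LI
    additionally carries truncated-Gaussian noise ``li_measurement_sd``.
    """

    n_per_stage: tuple[tuple[str, int], ...] = (
        ("preantral", 40),
        ("fsh_sensitive", 30),
        ("fsh_dependent", 60),
        ("preovulatory", 12),
    )
    li_preantral_mean: float = 0.20
    li_intercept: float = DEFAULT_LI_INTERCEPT
    li_decline_slope: float = DEFAULT_LI_DECLINE_SLOPE
    li_heterogeneity_sd: float = 0.06
    li_measurement_sd: float = 0.03
    diameter_log_sd: float = 0.25
    thresholds: StageThresholds = dataclasses.field(default_factory=StageThresholds)
    preovulatory_max: float = 462.0
    atresia_hazard: AtresiaHazard | None = dataclasses.field(
        default_factory=AtresiaHazard
    )

    def stage_interval(self, stage: str) -> tuple[float, float]:
        t = self.thresholds
        intervals = {
            "preantral": (t.preantral_min, t.fsh_sensitive_min),
            "fsh_sensitive": (t.fsh_sensitive_min, t.fsh_dependent_min),
            "fsh_dependent": (t.fsh_dependent_min, t.preovulatory_min),
            "preovulatory": (t.preovulatory_min, self.preovulatory_max),
        }
        if stage not in intervals:
            raise ValueError(f"unknown stage {stage!r}")
        return intervals[stage]


def mean_li_at_diameter(diameter: np.ndarray, config: PopulationConfig) -> np.ndarray:
    """Piecewise-linear mean LI trajectory over diameter (um)."""
    d = np.asarray(diameter, dtype=float)
    t = config.thresholds
    spurt_end = t.fsh_dependent_min
    li_spurt_end = config.li_intercept - config.li_decline_slope * spurt_end
    rise = config.li_preantral_mean + (
        (li_spurt_end - config.li_preantral_mean)
        * (d - t.fsh_sensitive_min)
        / (spurt_end - t.fsh_sensitive_min)
    )
    decline = config.li_intercept - config.li_decline_slope * d
    out = np.where(
        d < t.fsh_sensitive_min,
        config.li_preantral_mean,
        np.where(d < spurt_end, rise, decline),
    )
    return np.clip(out, 0.0, 1.0)


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Gaussian draws re-sampled into [lo, hi] (clip fallback after 50 rounds)."""
    mean = np.asarray(mean, dtype=float)
    out = rng.normal(mean, sd)
    for _ in range(50):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean[bad], sd)
    return np.clip(out, lo, hi)


def sample_population(
    config: PopulationConfig,
    cycle_stage: str = "diestrus",
    seed: int = 0,
    animal_id: str = "synthetic-1",
) -> pd.DataFrame:
    """Draw one animal's follicle population with ground-truth columns.

    Returns the standard follicle table (``follicle_id``, ``animal_id``,
    ``cycle_stage``, ``pseudodiameter_um``, ``li``, five ``atresia_*``
    flags, ``atretic``, ``included``) plus ``truth_li`` (the noise-free LI)
    and ``truth_atresia_p`` (the hazard applied).
    """
    if cycle_stage not in CYCLE_STAGES:
        raise ValueError(f"unknown cycle stage {cycle_stage!r}")
    rng = np.random.default_rng(seed)
    diam_parts, stage_parts = [], []
    for stage, n in config.n_per_stage:
        lo, hi = config.stage_interval(stage)
        mid = math.sqrt(lo * hi)  # geometric centre of the interval
        draws = np.exp(rng.normal(math.log(mid), config.diameter_log_sd, size=n))
        for _ in range(50):
            bad = (draws < lo) | (draws >= hi)
            if not bad.any():
                break
            draws[bad] = np.exp(
                rng.normal(math.log(mid), config.diameter_log_sd, size=bad.sum())
            )
        diam_parts.append(np.clip(draws, lo, np.nextafter(hi, lo)))
        stage_parts.extend([stage] * n)
    diameters = np.concatenate(diam_parts)
    true_li = _truncated_normal(
        rng, mean_li_at_diameter(diameters, config), config.li_heterogeneity_sd,
        0.0, 1.0,
    )
    measured_li = _truncated_normal(rng, true_li, config.li_measurement_sd, 0.0, 1.0)

    if config.atresia_hazard is not None:
        p_atresia = config.atresia_hazard.daily_probability(
            true_li, diameters, cycle_stage
        )
    else:
        p_atresia = np.zeros(len(diameters))
    atretic = rng.random(len(diameters)) < p_atresia

    n = len(diameters)
    flags = np.zeros((n, len(ATRESIA_CRITERIA)), dtype=bool)
    for i in np.flatnonzero(atretic):
        k = rng.integers(1, len(ATRESIA_CRITERIA) + 1)
        which = rng.choice(len(ATRESIA_CRITERIA), size=k, replace=False)
        flags[i, which] = True

    df = pd.DataFrame(
        {
            "follicle_id": [f"{animal_id}-f{i:04d}" for i in range(n)],
            "animal_id": animal_id,
            "cycle_stage": cycle_stage,
            "stage": stage_parts,
            "pseudodiameter_um": diameters,
            "li": measured_li,
            "atretic": atretic,
            "included": True,
            "truth_li": true_li,
            "truth_atresia_p": p_atresia,
        }
    )
    for j, name in enumerate(ATRESIA_CRITERIA):
        df[f"atresia_{name}"] = flags[:, j]
    return df


def simulate_pulse_chase(
    records: pd.DataFrame,
    design: Literal["2h", "48h"],
    params: GrowthModelParams | None = None,
    days_elapsed: int = 2,
    hazard: AtresiaHazard | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Project a labelled population to the end of the chase period.

    ``"2h"`` leaves the population at injection time: the measured LI simply
    reflects instantaneous proliferation.  ``"48h"`` grows every surviving
    follicle for ``days_elapsed`` (1-2) 24-h iterations of the growth model
    using its true injection-time LI, carries that LI forward as the label
    signal (the label is not diluted below detectability over 1-2 days), and
    optionally applies the atresia hazard each day, which preferentially
    removes slow-growing FSH-dependent follicles.

    Returns a copy of ``records`` with ``pseudodiameter_um`` advanced,
    ``label_li`` (the injection-time LI readout), and updated ``atretic``.
    """
    if design not in ("2h", "48h"):
        raise ValueError(f"unknown pulse-chase design {design!r}")
    out = records.copy()
    out["label_li"] = out["li"]
    if design == "2h":
        return out
    if not 1 <= days_elapsed <= 2:
        raise ValueError("48h design spans 1-2 elapsed days")
    params = params or GrowthModelParams()
    rng = np.random.default_rng(seed)
    true_li = (
        out["truth_li"] if "truth_li" in out.columns else out["li"]
    ).to_numpy(dtype=float)
    atretic = out["atretic"].to_numpy(dtype=bool).copy()
    diam = out["pseudodiameter_um"].to_numpy(dtype=float).copy()
    starts = [
        FollicleState.from_diameter(d, li, params)
        for d, li in zip(diam, np.clip(true_li, 0, 1))
    ]
    current = list(starts)
    stage = out["cycle_stage"].iloc[0] if len(out) else "diestrus"
    for _ in range(days_elapsed):
        for i in range(len(current)):
            if not atretic[i]:
                current[i] = grow_one_day(current[i], starts[i], params)
                diam[i] = current[i].diameter
        if hazard is not None:
            at_risk = np.flatnonzero(~atretic)
            if len(at_risk):
                p = hazard.daily_probability(
                    true_li[at_risk], diam[at_risk], stage
                )
                atretic[at_risk] |= rng.random(len(at_risk)) < p
    out["pseudodiameter_um"] = diam
    out["atretic"] = atretic
    return out


@dataclasses.dataclass(frozen=True)
class SyntheticHistologyConfig:
    """Geometry settings for rendered section stacks and masks.

    The mural shell thickness follows a linear relation in diameter whose
    default coefficients were fitted so that the spherical-shell volume
    matches the power-law mural volume within 10% over 170-450 um.
    """

    section_thickness: float = 5.0
    series_length: int = 75
    sampling_interval: int = 1
    pixel_size: float = 1.0
    mural_thickness_intercept: float = -1.4
    mural_thickness_slope: float = 0.0975

    def __post_init__(self) -> None:
        if self.section_thickness <= 0 or self.pixel_size <= 0:
            raise ValueError("section_thickness and pixel_size must be positive")
        if self.series_length < 1 or self.sampling_interval < 1:
            raise ValueError("series_length and sampling_interval must be >= 1")

    @classmethod
    def two_hour(cls, **kw) -> "SyntheticHistologyConfig":
        """75 consecutive 5-um sections (375-um sampling volume)."""
        return cls(series_length=75, sampling_interval=1, **kw)

    @classmethod
    def forty_eight_hour(cls, **kw) -> "SyntheticHistologyConfig":
        """Every 25th section: 125-um sampling intervals."""
        return cls(series_length=75, sampling_interval=25, **kw)

    def mural_thickness(self, diameter: float) -> float:
        """Shell thickness (um), floored at 3 um and at most the radius."""
        t = self.mural_thickness_intercept + self.mural_thickness_slope * diameter
        return float(np.clip(t, 3.0, diameter / 2.0))


def render_section_stack(
    diameter: float,
    config: SyntheticHistologyConfig | None = None,
    equator_offset: float = 0.0,
) -> SectionSeries:
    """Serial-section areas of a sphere sliced at section midplanes.

    ``equator_offset`` is the z position (um) of the sphere centre relative
    to the start of the sampling window (which spans
    ``series_length * section_thickness`` um).  Sections are sampled every
    ``sampling_interval`` positions; only sections intersecting the sphere
    enter the profile.
    """
    config = config or SyntheticHistologyConfig()
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    r = diameter / 2.0
    t = config.section_thickness
    profile = []
    for k in range(0, config.series_length, config.sampling_interval):
        z_mid = (k + 0.5) * t
        dz = z_mid - equator_offset
        if abs(dz) < r:
            area = math.pi * (r**2 - dz**2)
            profile.append((k, area))
    return SectionSeries(
        section_thickness=t,
        series_length=config.series_length,
        sampling_interval=config.sampling_interval,
        per_follicle_profile=tuple(profile),
    )


def _circle_polygon(
    center: tuple[float, float], radius: float, n_vertices: int = 256
) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.sin(theta), center[1] + radius * np.cos(theta)]
    )


def render_mask(
    diameter: float,
    li: float,
    config: SyntheticHistologyConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, RegionOfInterest, dict]:
    """Equatorial cross-section mask of one follicle with known LI.

    The image contains a mural granulosa annulus (classes brdu_neg/brdu_pos)
    around an antrum, an oocyte at the antrum centre wrapped in a cumulus
    ring of granulosa-class pixels (all BrdU-negative, so failing to exclude
    the cumulus biases the measured LI downward), and background outside.
    Exactly ``round(li * n_mural)`` mural pixels are BrdU-positive, laid out
    as a contiguous angular block starting at a seeded random angle
    (emulating the patchiness of real labeling).

    Returns ``(mask, roi, truth)`` where ``roi`` carries the basal-lamina
    circle (slightly dilated) and one cumulus exclusion polygon, and
    ``truth`` records the planted labeling index and pixel counts.
    """
    config = config or SyntheticHistologyConfig()
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if not 0 <= li <= 1:
        raise ValueError("li must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    px = config.pixel_size
    r_out = diameter / 2.0 / px
    t_mural = config.mural_thickness(diameter) / px
    margin = 5
    size = int(math.ceil(2 * r_out)) + 2 * margin
    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size]
    rr = np.hypot(rows - c, cols - c)

    mask = np.full((size, size), CLASS_CODES["background"], dtype=np.uint8)
    inside = rr <= r_out
    mask[inside] = CLASS_CODES["antrum"]
    mural = inside & (rr >= r_out - t_mural)
    r_antrum = r_out - t_mural
    r_oocyte = min(20.0 / px, 0.4 * r_antrum)
    cum_t = max(2.0, 3.0 / px)
    oocyte = rr <= r_oocyte
    cumulus = (rr > r_oocyte) & (rr <= r_oocyte + cum_t)
    mask[oocyte] = CLASS_CODES["oocyte"]
    mask[cumulus & ~mural] = CLASS_CODES["brdu_neg"]

    mural_idx = np.flatnonzero(mural.ravel())
    angles = np.arctan2(
        rows.ravel()[mural_idx] - c, cols.ravel()[mural_idx] - c
    )
    start = rng.uniform(-math.pi, math.pi)
    order = np.argsort(np.mod(angles - start, 2 * math.pi))
    n_mural = len(mural_idx)
    n_pos = int(round(li * n_mural))
    flat = mask.ravel()
    flat[mural_idx] = CLASS_CODES["brdu_neg"]
    flat[mural_idx[order[:n_pos]]] = CLASS_CODES["brdu_pos"]
    mask = flat.reshape(size, size)

    roi = RegionOfInterest(
        basal_lamina_polygon=_circle_polygon((c, c), min(r_out + 2.0, c)),
        cumulus_exclusion_polygons=(
            _circle_polygon((c, c), r_oocyte + cum_t + 1.5),
        ),
    )
    truth = {
        "li": n_pos / n_mural if n_mural else float("nan"),
        "requested_li": li,
        "n_mural_pixels": int(n_mural),
        "n_positive_pixels": int(n_pos),
        "diameter_um": diameter,
        "pixel_size": px,
    }
    return mask, roi, truth
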