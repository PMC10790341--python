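"""Labeling-index quantification and stereological measurement rules.

Works on multi-class segmentation masks of BrdU immunohistochemistry: each
pixel is coded background (0), BrdU-negative granulosa (1), BrdU-positive
granulosa (2), antrum (3), or oocyte (4).  The labeling index is the area
fraction of positive granulosa within a region of interest drawn around the
basal lamina, after cutting out the cumulus region (cumulus proliferation is
confined to the oocyte's vicinity and does not drive follicle growth).

Stereology: follicles are measured on serial 5-um sections; the
cross-sectional area at the widest observed section is converted to a
pseudodiameter (diameter of the equal-area circle).  A follicle whose widest
observed section is the first or last section of the sampled series is
excluded, because its true equator may lie outside the sampling volume.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from skimage.draw import polygon2mask

from .params import StageThresholds

__all__ = [
    "CLASS_CODES",
    "MaskQuantification",
    "RegionOfInterest",
    "SectionSeries",
    "FollicleRecord",
    "ATRESIA_CRITERIA",
    "labeling_index",
    "quantify_mask",
    "pseudodiameter",
    "widest_section",
    "include_follicle",
    "classify_atresia",
    "assign_stage",
]

#: Integer pixel classes used in mask files.
CLASS_CODES = {
    "background": 0,
    "brdu_neg": 1,
    "brdu_pos": 2,
    "antrum": 3,
    "oocyte": 4,
}

#: Morphological atresia criteria; a follicle showing any one is atretic.
ATRESIA_CRITERIA = (
    "pyknotic_antrum_nuclei",
    "non_contiguous_cumulus",
    "pleated_oocyte_membrane",
    "pyknotic_oocyte_nucleus",
    "zona_separation",
)


@dataclasses.dataclass(frozen=True)
class MaskQuantification:
    """Class areas (um^2) measured inside a region of interest."""

    area_brdu_positive: float
    area_brdu_negative: float
    area_other_classes: float
    pixel_size: float

    def __post_init__(self) -> None:
        if min(self.area_brdu_positive, self.area_brdu_negative,
               self.area_other_classes) < 0:
            raise ValueError("areas must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclasses.dataclass(frozen=True)
class RegionOfInterest:
    """Basal-lamina polygon with optional cumulus exclusion polygons.

    Coordinates are (row, col) pixel positions; polygons are closed
    implicitly (last vertex joins the first).
    """

    basal_lamina_polygon: np.ndarray
    cumulus_exclusion_polygons: tuple[np.ndarray, ...] = ()

    def __post_init__(self) -> None:
        poly = np.asarray(self.basal_lamina_polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError("basal polygon must be an (n, 2) array, n >= 3")
        object.__setattr__(self, "basal_lamina_polygon", poly)
        cleaned = tuple(
            np.asarray(p, dtype=float) for p in self.cumulus_exclusion_polygons
        )
        for p in cleaned:
            if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
                raise ValueError("exclusion polygons must be (n, 2) arrays, n >= 3")
        object.__setattr__(self, "cumulus_exclusion_polygons", cleaned)

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask: inside basal polygon minus exclusions."""
        inside = polygon2mask(shape, self.basal_lamina_polygon)
        for p in self.cumulus_exclusion_polygons:
            inside &= ~polygon2mask(shape, p)
        return inside


@dataclasses.dataclass(frozen=True)
class SectionSeries:
    """Sampled serial-section profile of one follicle.

    ``per_follicle_profile`` holds (section index, cross-sectional area um^2)
    pairs at the sampled sections where the follicle is visible; indices are
    positions within the full series (0-based).  ``first_index``/
    ``last_index`` delimit the sampled window of the series.
    """

    section_thickness: float
    series_length: int
    sampling_interval: int
    per_follicle_profile: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if self.section_thickness <= 0:
            raise ValueError("section_thickness must be positive")
        if self.series_length < 1 or self.sampling_interval < 1:
            raise ValueError("series_length and sampling_interval must be >= 1")
        prof = tuple((int(i), float(a)) for i, a in self.per_follicle_profile)
        idx = [i for i, _ in prof]
        if any(a < 0 for _, a in prof):
            raise ValueError("areas must be non-negative")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("section indices must be strictly increasing")
        if any(i % self.sampling_interval for i in idx):
            raise ValueError("profile indices must fall on sampled sections")
        if idx and (idx[0] < 0 or idx[-1] > self.last_index):
            raise ValueError("profile indices outside the series")
        object.__setattr__(self, "per_follicle_profile", prof)

    @property
    def first_index(self) -> int:
        return 0

    @property
    def last_index(self) -> int:
        """Index of the last sampled section in the series."""
        return ((self.series_length - 1) // self.sampling_interval) * self.sampling_interval


@dataclasses.dataclass
class FollicleRecord:
    """One measured follicle — the experimental unit of the analysis."""

    follicle_id: str
    animal_id: str
    cycle_stage: str
    pseudodiameter_um: float
    li: float
    atresia_flags: dict[str, bool]
    included: bool = True

    def __post_init__(self) -> None:
        if self.pseudodiameter_um <= 0:
            raise ValueError("pseudodiameter must be positive")
        if not 0 <= self.li <= 1:
            raise ValueError("labeling index must lie in [0, 1]")
        if self.cycle_stage not in {"estrus", "metestrus", "diestrus", "proestrus"}:
            raise ValueError(f"unknown cycle stage {self.cycle_stage!r}")

    @property
    def atretic(self) -> bool:
        return classify_atresia(self.atresia_flags) == "atretic"


def labeling_index(q: MaskQuantification) -> float:
    """Area fraction of BrdU-positive granulosa: A+ / (A+ + A-).

    Scale-invariant (pixel size cancels).  Undefined when no granulosa area
    lies in the region of interest.
    """
    denom = q.area_brdu_positive + q.area_brdu_negative
    if denom <= 0:
        raise ValueError("labeling index undefined: no granulosa area in ROI")
    return q.area_brdu_positive / denom


def quantify_mask(
    mask: np.ndarray,
    roi: RegionOfInterest,
    pixel_size: float = 1.0,
) -> MaskQuantification:
    """Sum class areas inside the basal-lamina ROI minus cumulus exclusions.

    ``mask`` is a 2-D integer image using :data:`CLASS_CODES`.  Classes other
    than the two granulosa classes are tallied as ``area_other_classes`` and
    never enter the labeling index.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D class-coded image")
    codes = np.unique(mask)
    known = np.array(sorted(CLASS_CODES.values()))
    if not np.isin(codes, known).all():
        bad = sorted(set(codes.tolist()) - set(known.tolist()))
        raise ValueError(f"unknown class codes in mask: {bad}")
    poly = roi.basal_lamina_polygon
    if poly.min() < -0.5 or (poly[:, 0] > mask.shape[0] - 0.5).any() or (
        poly[:, 1] > mask.shape[1] - 0.5
    ).any():
        raise ValueError("ROI polygon extends outside the image")
    inside = roi.rasterize(mask.shape)
    px_area = pixel_size**2
    vals = mask[inside]
    a_pos = float(np.count_nonzero(vals == CLASS_CODES["brdu_pos"]) * px_area)
    a_neg = float(np.count_nonzero(vals == CLASS_CODES["brdu_neg"]) * px_area)
    a_other = float(len(vals) * px_area - a_pos - a_neg)
    return MaskQuantification(
        area_brdu_positive=a_pos,
        area_brdu_negative=a_neg,
        area_other_classes=a_other,
        pixel_size=pixel_size,
    )


def pseudodiameter(cross_sectional_area: float) -> float:
    """Diameter (um) of the circle with the given area (um^2)."""
    if cross_sectional_area < 0:
        raise ValueError("area must be non-negative")
    return 2.0 * math.sqrt(cross_sectional_area / math.pi)


def widest_section(series: SectionSeries) -> tuple[int, float]:
    """Profile entry with the maximal area; ties go to the lowest index."""
    if not series.per_follicle_profile:
        raise ValueError("empty follicle profile")
    return max(series.per_follicle_profile, key=lambda e: (e[1], -e[0]))


def include_follicle(series: SectionSeries) -> bool:
    """False iff the widest observed section is the first or last sampled one.

    In that case the follicle's true equator may lie outside the sampling
    volume and the measured pseudodiameter would be an underestimate.
    """
    idx, _ = widest_section(series)
    return idx not in (series.first_index, series.last_index)


def classify_atresia(flags: dict[str, bool] | Sequence[bool]) -> str:
    """"atretic" if any morphological criterion is present, else "non_atretic".

    Accepts a mapping keyed by :data:`ATRESIA_CRITERIA` (all five required)
    or a sequence of five booleans in that order.
    """
    if isinstance(flags, dict):
        missing = set(ATRESIA_CRITERIA) - set(flags)
        if missing:
            raise ValueError(f"missing atresia flags: {sorted(missing)}")
        values = [bool(flags[k]) for k in ATRESIA_CRITERIA]
    else:
        values = [bool(v) for v in flags]
        if len(values) != len(ATRESIA_CRITERIA):
            raise ValueError(f"expected {len(ATRESIA_CRITERIA)} atresia flags")
    return "atretic" if any(values) else "non_atretic"


def assign_stage(
    diameter: float, thresholds: StageThresholds | None = None
) -> str:
    """Stage label for a diameter: half-open [lower, upper) intervals.

    The preovulatory class is strict (> threshold); diameters below the
    preantral minimum return "sub-threshold".
    """
    t = thresholds or StageThresholds()
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if diameter > t.preovulatory_min:
        return "preovulatory"
    if diameter >= t.fsh_dependent_min:
        return "fsh_dependent"
    if diameter >= t.fsh_sensitive_min:
        return "fsh_sensitive"
    if diameter >= t.preantral_min:
        return "preantral"
    return "sub-threshold"
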