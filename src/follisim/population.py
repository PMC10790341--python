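"""Population-level analyses: regressions, counts, cohort recruitment.

The preovulatory cohort in the mouse (~10 follicles) accumulates over the
estrous cycle.  `simulate_cohort` grows a starting population of follicles
with the iterative granulosa-proliferation model, optionally thinning them
with an LI-dependent atresia hazard, and reports the first day on which the
cohort target of preovulatory-sized follicles (>350 um by default) is met.
The minimum cycle length is that day plus one (the proestrus/ovulation day).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .growth import FollicleState, GrowthModelParams, grow_one_day
from .regression import LiDeclineModel, LiDeclineResults, SubsetRule

__all__ = [
    "CohortScenario",
    "CohortReport",
    "fit_li_regression",
    "count_preovulatory",
    "simulate_cohort",
    "survivor_effect",
]


@dataclasses.dataclass(frozen=True)
class CohortScenario:
    """Starting population and rules for a recruitment simulation."""

    starting_follicles: tuple[tuple[float, float], ...]  # (diameter um, LI)
    cohort_target: int = 10
    preovulatory_min: float = 350.0
    max_days: int = 30
    atresia_hazard: "AtresiaHazard | None" = None

    def __post_init__(self) -> None:
        if self.cohort_target < 1:
            raise ValueError("cohort_target must be >= 1")
        follicles = tuple((float(d), float(li)) for d, li in self.starting_follicles)
        if any(d <= 0 for d, _ in follicles):
            raise ValueError("starting diameters must be positive")
        if any(not 0 <= li <= 1 for _, li in follicles):
            raise ValueError("starting LIs must lie in [0, 1]")
        if self.max_days < 1:
            raise ValueError("max_days must be >= 1")
        object.__setattr__(self, "starting_follicles", follicles)


def fit_li_regression(
    records: pd.DataFrame,
    subset_rule: SubsetRule = "median_all",
    diameter_range: tuple[float, float] = (170.0, 350.0),
) -> LiDeclineResults:
    """Fit the LI-vs-diameter decline on included, non-atretic follicles.

    Convenience wrapper over :class:`follisim.regression.LiDeclineModel`.
    """
    model = LiDeclineModel.from_records(
        records, subset_rule=subset_rule, diameter_range=diameter_range
    )
    return model.fit()


def count_preovulatory(
    records: pd.DataFrame, preovulatory_min: float = 350.0
) -> pd.DataFrame:
    """Count non-atretic, included follicles above threshold per animal/stage.

    Requires ``animal_id``, ``cycle_stage``, ``pseudodiameter_um``,
    ``atretic`` and ``included`` columns.  Returns a table indexed by
    (animal_id, cycle_stage) with a ``n_preovulatory`` column; animals/stages
    present in the input but with no qualifying follicles appear with zero.
    """
    required = {"animal_id", "cycle_stage", "pseudodiameter_um", "atretic", "included"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if len(records) == 0:
        return pd.DataFrame(
            columns=["animal_id", "cycle_stage", "n_preovulatory"]
        ).set_index(["animal_id", "cycle_stage"])
    qualifying = (
        (records["pseudodiameter_um"] > preovulatory_min)
        & ~records["atretic"].astype(bool)
        & records["included"].astype(bool)
    )
    out = (
        qualifying.groupby([records["animal_id"], records["cycle_stage"]])
        .sum()
        .astype(int)
        .rename("n_preovulatory")
        .to_frame()
    )
    return out


def simulate_cohort(
    scenario: CohortScenario,
    params: GrowthModelParams | None = None,
    seed: int | None = 0,
) -> "CohortReport":
    """Grow a follicle population day by day and track cohort recruitment.

    Each follicle follows its own deterministic growth trajectory; if the
    scenario carries an atresia hazard, follicles may be removed at the end
    of each day (random draws from ``seed``).  Recruitment is the cumulative
    count of surviving follicles at or above ``preovulatory_min``.
    """
    params = params or GrowthModelParams()
    rng = np.random.default_rng(seed)
    starts = [
        FollicleState.from_diameter(d, li, params)
        for d, li in scenario.starting_follicles
    ]
    current = list(starts)
    alive = np.ones(len(starts), dtype=bool)
    lis = np.array([li for _, li in scenario.starting_follicles])
    rows = []
    day_met: int | None = None

    def record_day(day: int) -> int:
        n_preov = 0
        for fid, state in enumerate(current):
            status = "atretic" if not alive[fid] else (
                "preovulatory"
                if state.diameter >= scenario.preovulatory_min
                else "growing"
            )
            if status == "preovulatory":
                n_preov += 1
            rows.append(
                {
                    "day": day,
                    "follicle_id": fid,
                    "diameter_um": state.diameter,
                    "status": status,
                    "cumulative_preovulatory": np.nan,  # filled below
                }
            )
        for r in rows[-len(current):]:
            r["cumulative_preovulatory"] = n_preov
        return n_preov

    n0 = record_day(0)
    if n0 >= scenario.cohort_target:
        day_met = 0
    for day in range(1, scenario.max_days + 1):
        if day_met is not None:
            break
        for fid in range(len(current)):
            if alive[fid]:
                current[fid] = grow_one_day(current[fid], starts[fid], params)
        if scenario.atresia_hazard is not None:
            # hazard acts on follicles still short of the preovulatory size
            at_risk = [
                fid
                for fid in range(len(current))
                if alive[fid] and current[fid].diameter < scenario.preovulatory_min
            ]
            if at_risk:
                probs = scenario.atresia_hazard.daily_probability(
                    lis[at_risk], np.array([current[f].diameter for f in at_risk])
                )
                dead = rng.random(len(at_risk)) < probs
                for fid, d in zip(at_risk, dead):
                    if d:
                        alive[fid] = False
        n = record_day(day)
        if n >= scenario.cohort_target:
            day_met = day
    per_day = pd.DataFrame(rows)
    return CohortReport(
        per_day=per_day,
        day_target_met=day_met,
        cohort_target=scenario.cohort_target,
    )


@dataclasses.dataclass(frozen=True)
class CohortReport:
    """Per-day follicle table plus recruitment summary."""

    per_day: pd.DataFrame
    day_target_met: int | None
    cohort_target: int

    @property
    def target_met(self) -> bool:
        return self.day_target_met is not None

    @property
    def minimum_cycle_length(self) -> int | None:
        """Day the target is met plus one proestrus/ovulation day."""
        if self.day_target_met is None:
            return None
        return self.day_target_met + 1


def survivor_effect(
    population_li: Sequence[float],
    survivor_li: Sequence[float],
) -> dict[str, float]:
    """Compare injection-time labeling indices of survivors vs everyone.

    ``population_li`` are the pulse LIs of the full population at injection;
    ``survivor_li`` those of the follicles that later reached preovulatory
    size.  A positive mean/median difference indicates preferential loss of
    slow-growing follicles.  The Mann-Whitney U p-value (survivors greater)
    is included as a standard rank-based check.
    """
    pop = np.asarray(population_li, dtype=float)
    surv = np.asarray(survivor_li, dtype=float)
    if len(surv) == 0:
        raise ValueError("empty survivor set")
    if len(pop) == 0:
        raise ValueError("empty population")
    out = {
        "population_mean_li": float(pop.mean()),
        "population_median_li": float(np.median(pop)),
        "survivor_mean_li": float(surv.mean()),
        "survivor_median_li": float(np.median(surv)),
        "n_population": int(len(pop)),
        "n_survivors": int(len(surv)),
    }
    out["mean_difference"] = out["survivor_mean_li"] - out["population_mean_li"]
    out["median_difference"] = (
        out["survivor_median_li"] - out["population_median_li"]
    )
    if len(surv) < len(pop) and np.ptp(pop) > 0:
        out["mannwhitney_p"] = float(
            stats.mannwhitneyu(surv, pop, alternative="greater").pvalue
        )
    else:
        out["mannwhitney_p"] = float("nan")
    return out
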