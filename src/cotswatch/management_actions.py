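"""Sector management-action classification and reef culling-effort strata.

A sector's action label combines when culling started relative to the
outbreak threshold crossings with whether the effort achieved suppression.
Suppression means the sector density fell back below the potential threshold
for a sustained run *and* the coral was retained — an outbreak that ends by
eating out its prey is not a management success.  Reefs are stratified by
culling effort relative to outbreak severity using the ratio of total cull
hours to maximum COTS density, split at the median over actively culled
outbreak reefs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

import numpy as np
import pandas as pd

from .outbreak_dynamics import SectorOutbreakTimeline, _first_run_start
from .surveillance_io import ThresholdConfig

logger = logging.getLogger(__name__)


class Action(str, Enum):
    Proactive = "Proactive"
    Timely = "Timely"
    Reactive = "Reactive"
    Limited = "Limited"
    NoAction = "NoAction"


class EffortCategory(str, Enum):
    NoOutbreak = "NoOutbreak"
    AboveMedian = "AboveMedian"
    BelowMedian = "BelowMedian"
    NoEffort = "NoEffort"


@dataclass(frozen=True)
class ManagementClassification:
    sector_id: object
    action: Action
    cull_start_year: int | None
    suppression_achieved: bool
    rationale: str


def _first_year(years: np.ndarray, mask: np.ndarray) -> int | None:
    idx = np.nonzero(mask)[0]
    return int(years[idx[0]]) if idx.size else None


def classify_action(
    timeline: SectorOutbreakTimeline,
    cull_hours_by_year: dict[int, float],
    config: ThresholdConfig,
    cover_by_year: dict[int, float] | None = None,
) -> ManagementClassification:
    """Label a sector's management action from its density and cull history.

    * NoAction — no culling hours at all.
    * Proactive — culling started strictly before the sector ever crossed the
      potential threshold.
    * Timely — culling started at/after the potential crossing and suppression
      was achieved (post-cull densities below potential for a sustained run,
      with coral cover retained above ``1 - depletion_fraction`` of the
      window-start cover).
    * Reactive — culling started before the severe crossing but suppression
      failed.
    * Limited — culling started at/after the severe crossing, or effort was
      otherwise insufficient.
    """
    years = np.asarray(timeline.years)
    dens = np.asarray(timeline.density, dtype=float)
    hours = np.array([float(cull_hours_by_year.get(int(y), 0.0)) for y in years])
    trace: list[str] = []

    if hours.sum() <= 0:
        return ManagementClassification(
            timeline.sector_id, Action.NoAction, None, False, "no culling hours"
        )

    y_cull = _first_year(years, hours > 0)
    y_pot = _first_year(years, dens > config.potential)
    y_sev = _first_year(years, dens >= config.severe)
    trace.append(f"y_cull={y_cull}, y_pot={y_pot}, y_sev={y_sev}")

    if y_pot is None or y_cull < y_pot:
        trace.append("culling precedes any potential-threshold crossing")
        return ManagementClassification(
            timeline.sector_id, Action.Proactive, y_cull, False, "; ".join(trace)
        )

    suppressed = _suppression_achieved(
        years, dens, y_cull, timeline, config, cover_by_year, trace
    )

    if suppressed:
        action = Action.Timely
    elif y_sev is None or y_cull < y_sev:
        action = Action.Reactive
    else:
        action = Action.Limited
    trace.append(f"suppression_achieved={suppressed}")
    return ManagementClassification(
        timeline.sector_id, action, y_cull, suppressed, "; ".join(trace)
    )


def _suppression_achieved(
    years: np.ndarray,
    dens: np.ndarray,
    y_cull: int,
    timeline: SectorOutbreakTimeline,
    config: ThresholdConfig,
    cover_by_year: dict[int, float] | None,
    trace: list[str],
) -> bool:
    """Two-part test: sustained sub-potential densities after culling began,
    and coral cover retained over the outbreak window."""
    after = years >= y_cull
    below = (dens < config.potential) & after
    start_idx = int(np.nonzero(after)[0][0])
    run_idx = _first_run_start(below, config.decline_years, start_idx)
    if run_idx is None:
        trace.append("densities never sustained below potential after culling")
        return False
    if cover_by_year is None:
        raise ValueError(
            f"sector {timeline.sector_id}: cover series required for the "
            f"suppression test"
        )
    # Window for the cover-retention check: the detected outbreak window, or —
    # when suppression prevented a window from ever forming — the span from
    # one year before the potential crossing to the end of the sub-threshold run.
    if timeline.outbreak is not None:
        w_start, w_end = timeline.outbreak.start_year, timeline.outbreak.end_year
    else:
        y_pot = _first_year(years, dens > config.potential)
        w_start = max(int(years[0]), y_pot - 1)
        w_end = int(years[run_idx + config.decline_years - 1])
    c_start = _nearest_cover(cover_by_year, w_start, direction=1)
    c_end = _nearest_cover(cover_by_year, w_end, direction=-1)
    if c_start is None or c_end is None or c_start <= 0:
        trace.append("cover unavailable at window bounds")
        return False
    retained = c_end >= (1.0 - config.depletion_fraction) * c_start
    trace.append(
        f"cover window [{w_start},{w_end}]: start={c_start:.3f}, "
        f"end={c_end:.3f}, retained={retained}"
    )
    return retained


def _nearest_cover(
    cover_by_year: dict[int, float], year: int, direction: int
) -> float | None:
    """Cover at `year`, else the nearest survey stepping by `direction`."""
    years = sorted(cover_by_year)
    if not years:
        return None
    if year in cover_by_year:
        return float(cover_by_year[year])
    candidates = [y for y in years if (y - year) * direction > 0]
    return float(cover_by_year[candidates[0] if direction > 0 else candidates[-1]]) if candidates else None


def effort_ratio(total_hours: float, max_density: float) -> float:
    """Culling hours per unit of maximum COTS density (hours per COTS/tow)."""
    if max_density <= 0:
        raise ValueError(
            "effort ratio undefined at zero density; route reef to NoOutbreak"
        )
    return total_hours / max_density


def effort_threshold_hours(median_ratio: float, density: float) -> float:
    """Hours needed at a given density to sit at the median effort ratio."""
    if median_ratio < 0 or density < 0:
        raise ValueError("median_ratio and density must be non-negative")
    return median_ratio * density


def stratify_effort(
    reefs: pd.DataFrame, config: ThresholdConfig
) -> pd.DataFrame:
    """Partition reefs into effort categories around the median effort ratio.

    ``reefs`` needs columns reef_id, total_hours, max_density (max COTS/tow
    over the reef's sector outbreak window).  Reefs below the reef outbreak
    threshold are the NoOutbreak control group; outbreak reefs with zero
    hours are NoEffort; the rest are split at the median ratio computed over
    outbreak reefs with positive hours (ties go AboveMedian).
    """
    df = reefs.copy()
    outbreak = df["max_density"] >= config.reef_outbreak_threshold
    effort = df["total_hours"] > 0
    active = outbreak & effort
    if active.any():
        ratios = df.loc[active, "total_hours"] / df.loc[active, "max_density"]
        median_ratio = float(ratios.median())
    else:
        median_ratio = np.nan
        logger.warning(
            "no outbreak reefs with culling effort; stratification degenerates "
            "to NoOutbreak/NoEffort only"
        )

    def categorise(row):
        if row["max_density"] < config.reef_outbreak_threshold:
            return EffortCategory.NoOutbreak.value
        if row["total_hours"] <= 0:
            return EffortCategory.NoEffort.value
        ratio = row["total_hours"] / row["max_density"]
        return (
            EffortCategory.AboveMedian.value
            if ratio >= median_ratio
            else EffortCategory.BelowMedian.value
        )

    df["effort_ratio"] = np.where(
        df["max_density"] > 0, df["total_hours"] / df["max_density"], np.nan
    )
    df["category"] = df.apply(categorise, axis=1)
    df["median_ratio_used"] = median_ratio
    return df[
        [
            "reef_id",
            "total_hours",
            "max_density",
            "effort_ratio",
            "category",
            "median_ratio_used",
        ]
    ].reset_index(drop=True)


def effort_share(sector_hours: float, all_sector_hours) -> float:
    """Sector share of total culling hours, percent, rounded half-up to 0.1."""
    total = float(np.sum(all_sector_hours))
    if total <= 0:
        raise ValueError("total culling hours must be positive")
    share = Decimal(100 * sector_hours / total).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(share)
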