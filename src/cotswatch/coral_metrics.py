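"""Coral-cover category conversion and change metrics.

Manta-tow observers record hard-coral cover as an ordinal category on the
standard six-level scheme (0, 1-10%, 11-30%, 31-50%, 51-75%, 76-100%).
Analyses work on the category mid-points expressed as proportions.  Change
metrics are exact arithmetic on start/end covers: relative change is percent
of the starting cover, annual absolute change is percentage points per year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CategoryScheme:
    """Ordinal cover categories: upper bin edges and mid-points (proportions)."""

    upper_edges: tuple = (0.0, 0.10, 0.30, 0.50, 0.75, 1.0)
    midpoints: tuple = (0.0, 0.055, 0.205, 0.405, 0.63, 0.88)

    def __post_init__(self) -> None:
        mids = np.asarray(self.midpoints)
        if not np.all(np.diff(mids) > 0):
            raise ValueError("midpoints must be strictly increasing")
        edges = np.asarray(self.upper_edges)
        lower = np.concatenate([[-np.inf], edges[:-1]])
        if not np.all((mids > lower) | (mids == edges)):
            raise ValueError("each midpoint must lie inside its bin")

    @property
    def n_categories(self) -> int:
        return len(self.midpoints)

    def to_category(self, cover) -> np.ndarray:
        """Bin a cover proportion into its ordinal category.

        Category 0 is reserved for exactly zero cover; positive covers fall in
        the half-open bins (0, 0.10], (0.10, 0.30], ... per the field scheme.
        """
        cover = np.asarray(cover, dtype=float)
        edges = np.asarray(self.upper_edges[1:-1])  # interior upper edges
        cat = np.searchsorted(edges, cover, side="left") + 1
        cat = np.where(cover <= 0.0, 0, cat)
        return np.clip(cat, 0, self.n_categories - 1).astype(int)


DEFAULT_SCHEME = CategoryScheme()


def category_to_midpoint(category, scheme: CategoryScheme = DEFAULT_SCHEME):
    """Map ordinal cover categories to mid-point proportions."""
    category = np.asarray(category)
    if np.any((category < 0) | (category >= scheme.n_categories)):
        raise ValueError(f"cover category outside 0-{scheme.n_categories - 1}")
    mids = np.asarray(scheme.midpoints)
    out = mids[category]
    return float(out) if out.ndim == 0 else out


def reef_year_cover(
    tows: pd.DataFrame, scheme: CategoryScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Point estimate of reef cover per year: mean of tow category mid-points.

    Returns columns reef_id, sector_id (if present), year, cover, n_tows.
    """
    df = tows.copy()
    df["midpoint"] = category_to_midpoint(df["cover_category"].to_numpy(), scheme)
    keys = ["reef_id", "year"]
    if "sector_id" in df.columns:
        keys = ["reef_id", "sector_id", "year"]
    out = (
        df.groupby(keys)
        .agg(cover=("midpoint", "mean"), n_tows=("midpoint", "size"))
        .reset_index()
        .sort_values(["reef_id", "year"])
        .reset_index(drop=True)
    )
    return out


def relative_change(cover_start: float, cover_end: float) -> float:
    """Percent change of cover relative to the starting cover."""
    if cover_start <= 0:
        raise ValueError("relative change undefined for zero starting cover")
    return 100.0 * (cover_end - cover_start) / cover_start


def annual_absolute_change(
    cover_start: float, cover_end: float, duration_years: float
) -> float:
    """Absolute cover change in percentage points per year over a window."""
    if duration_years <= 0:
        raise ValueError("duration must be at least one year")
    return 100.0 * (cover_end - cover_start) / duration_years


def wave_change_metrics(
    covers: pd.DataFrame, windows: pd.DataFrame
) -> pd.DataFrame:
    """Per-reef change metrics over each sector's outbreak window.

    ``covers`` is the reef_year_cover table; ``windows`` has one row per
    sector with start_year and end_year.  Start/end covers take the survey
    nearest to (at or after) the window start and nearest to (at or before)
    the window end.  Reefs with zero starting cover or fewer than two surveys
    inside the window are excluded with a logged reason.
    """
    rows = []
    win = windows.set_index("sector_id")
    for (reef, sector), grp in covers.groupby(["reef_id", "sector_id"]):
        if sector not in win.index:
            continue
        start_y = int(win.loc[sector, "start_year"])
        end_y = int(win.loc[sector, "end_year"])
        inside = grp[(grp["year"] >= start_y) & (grp["year"] <= end_y)]
        if len(inside) < 2:
            logger.info("reef %s: <2 surveys inside window, excluded", reef)
            continue
        first = inside.iloc[inside["year"].argmin()]
        last = inside.iloc[inside["year"].argmax()]
        if first["cover"] <= 0:
            logger.info("reef %s: zero starting cover, excluded", reef)
            continue
        duration = int(last["year"] - first["year"])
        if duration == 0:
            continue
        rows.append(
            {
                "reef_id": reef,
                "sector_id": sector,
                "start_year": int(first["year"]),
                "end_year": int(last["year"]),
                "cover_start": float(first["cover"]),
                "cover_end": float(last["cover"]),
                "relative_change_pct": relative_change(
                    float(first["cover"]), float(last["cover"])
                ),
                "annual_pp_per_year": annual_absolute_change(
                    float(first["cover"]), float(last["cover"]), duration
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "reef_id",
            "sector_id",
            "start_year",
            "end_year",
            "cover_start",
            "cover_end",
            "relative_change_pct",
            "annual_pp_per_year",
        ],
    )


def align_to_onset(
    covers: pd.DataFrame,
    windows: pd.DataFrame,
    *,
    horizon_years: int = 6,
    min_surveys: int = 3,
) -> pd.DataFrame:
    """Per-reef relative cover change at 0..horizon years since window start.

    The baseline is the cover at the window start year, or the nearest prior
    survey when the start year was not surveyed; a reef with no survey at or
    before onset is excluded (logged).  Reefs with fewer than ``min_surveys``
    surveys in the horizon are flagged ``sparse`` rather than dropped.

    Returns columns reef_id, sector_id, years_since_onset,
    relative_change_pct, baseline_year, sparse.
    """
    rows = []
    win = windows.set_index("sector_id")
    for (reef, sector), grp in covers.groupby(["reef_id", "sector_id"]):
        if sector not in win.index:
            continue
        start_y = int(win.loc[sector, "start_year"])
        end_y = min(int(win.loc[sector, "end_year"]), start_y + horizon_years)
        at_or_before = grp[grp["year"] <= start_y]
        if at_or_before.empty:
            logger.info("reef %s: no baseline survey at or before onset", reef)
            continue
        base = at_or_before.iloc[at_or_before["year"].argmax()]
        if base["cover"] <= 0:
            logger.info("reef %s: zero baseline cover, excluded", reef)
            continue
        inside = grp[(grp["year"] >= start_y) & (grp["year"] <= end_y)]
        sparse = len(inside) < min_surveys
        for _, r in inside.iterrows():
            rows.append(
                {
                    "reef_id": reef,
                    "sector_id": sector,
                    "years_since_onset": int(r["year"] - start_y),
                    "relative_change_pct": relative_change(
                        float(base["cover"]), float(r["cover"])
                    ),
                    "baseline_year": int(base["year"]),
                    "sparse": bool(sparse),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "reef_id",
            "sector_id",
            "years_since_onset",
            "relative_change_pct",
            "baseline_year",
            "sparse",
        ],
    )
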