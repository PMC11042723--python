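"""Reef/sector COTS density series and sector-wide outbreak periods.

Density is COTS per manta tow.  When a reef is surveyed by multiple programs
in a year, the maximum per-program mean is the representative reef density
(pre-cull surveys by field-management and control programs can see densities
the annual monitoring misses).  Sector series are unweighted means of reef
densities; an outbreak window opens when the sector persists above its
inception threshold and escalates past the established threshold, and closes
after a run of sub-potential years.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .surveillance_io import Registry, ThresholdConfig


class ReefStatus(str, Enum):
    below = "below"
    potential = "potential"
    established = "established"
    severe = "severe"


@dataclass(frozen=True)
class OutbreakWindow:
    """A detected sector-wide outbreak period and its criterion years."""

    start_year: int
    end_year: int
    ongoing: bool
    inception_year: int
    escalation_year: int
    decline_year: int | None

    def __post_init__(self) -> None:
        if not (self.start_year <= self.inception_year <= self.escalation_year):
            raise ValueError("window criterion years out of order")
        if not self.ongoing and self.decline_year is not None:
            if self.decline_year > self.end_year:
                raise ValueError("decline_year after end_year")


@dataclass
class SectorOutbreakTimeline:
    """Annual sector density series with any detected outbreak window."""

    sector_id: object
    years: np.ndarray
    density: np.ndarray
    imputed: np.ndarray
    outbreak: OutbreakWindow | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sector_id": self.sector_id,
                "year": self.years,
                "density": self.density,
                "imputed": self.imputed,
            }
        )


def reef_year_density(tows: pd.DataFrame) -> pd.DataFrame:
    """Representative COTS density per (reef, year): max of per-program means.

    Returns reef_id, sector_id (if present), year, mean_cots_per_tow,
    n_tows (tows behind the winning program), source_program, programs_seen.
    """
    cols = ["reef_id", "year", "mean_cots_per_tow", "n_tows", "source_program", "programs_seen"]
    if "sector_id" in tows.columns:
        cols.insert(1, "sector_id")
    if tows.empty:
        return pd.DataFrame(columns=cols)
    keys = ["reef_id", "year"]
    if "sector_id" in tows.columns:
        keys = ["reef_id", "sector_id", "year"]
    per_prog = (
        tows.groupby(keys + ["program"])
        .agg(mean_cots_per_tow=("cots_count", "mean"), n_tows=("cots_count", "size"))
        .reset_index()
    )
    # stable winner on ties: first program in sorted order
    per_prog = per_prog.sort_values(keys + ["program"], kind="mergesort")
    idx = per_prog.groupby(keys)["mean_cots_per_tow"].idxmax()
    out = per_prog.loc[idx].rename(columns={"program": "source_program"})
    seen = per_prog.groupby(keys)["program"].agg(lambda p: ",".join(sorted(p)))
    out = out.merge(seen.rename("programs_seen").reset_index(), on=keys)
    return out[cols].sort_values(["reef_id", "year"]).reset_index(drop=True)


def classify_reef_status(density: float, config: ThresholdConfig) -> ReefStatus:
    """Grade a density on the potential/established/severe ladder.

    Threshold crossings are strict (a density of exactly 0.11 is still
    ``below``); the severe boundary is inclusive.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    if density >= config.severe:
        return ReefStatus.severe
    if density > config.established:
        return ReefStatus.established
    if density > config.potential:
        return ReefStatus.potential
    return ReefStatus.below


def sector_density_series(
    densities: pd.DataFrame, registry: Registry
) -> list[SectorOutbreakTimeline]:
    """Unweighted sector mean density per year, wave order, gaps interpolated.

    Interior missing years are linearly interpolated and flagged imputed;
    leading/trailing gaps are not extrapolated.
    """
    timelines = []
    df = densities.copy()
    if "sector_id" not in df.columns:
        df["sector_id"] = df["reef_id"].map(registry.reef_to_sector)
    for sector in registry.sectors:
        sub = df[df["sector_id"] == sector]
        if sub.empty:
            continue
        by_year = sub.groupby("year")["mean_cots_per_tow"].mean()
        years = np.arange(by_year.index.min(), by_year.index.max() + 1)
        series = by_year.reindex(years)
        imputed = series.isna().to_numpy()
        series = series.interpolate(method="index")
        timelines.append(
            SectorOutbreakTimeline(
                sector_id=sector,
                years=years,
                density=series.to_numpy(),
                imputed=imputed,
            )
        )
    return timelines


def _first_run_start(mask: np.ndarray, run: int, from_idx: int = 0) -> int | None:
    """Index of the first position >= from_idx starting `run` consecutive True."""
    n = len(mask)
    for i in range(from_idx, n - run + 1):
        if mask[i : i + run].all():
            return i
    return None


def detect_outbreak_period(
    timeline: SectorOutbreakTimeline,
    config: ThresholdConfig,
    uses_established_inception: bool = False,
) -> SectorOutbreakTimeline:
    """Delimit the sector-wide outbreak window, if the criteria are met.

    Inception: first year of a ``persistence_years`` run above the inception
    threshold (the potential threshold, or the established threshold for
    sectors flagged in the registry).  Escalation: first year at or after
    inception above the established threshold.  The window opens one year
    before the first potential-threshold crossing (clipped to the observed
    span) and closes with the ``decline_years`` consecutive sub-potential
    years; with no decline the outbreak is ongoing through the last year.
    """
    years = np.asarray(timeline.years)
    dens = np.asarray(timeline.density, dtype=float)
    if len(years) < max(3, config.persistence_years):
        raise ValueError(
            f"sector {timeline.sector_id}: series of length {len(years)} too "
            f"short for outbreak detection"
        )
    t_inc = config.established if uses_established_inception else config.potential

    above_inc = dens > t_inc
    inc_idx = _first_run_start(above_inc, config.persistence_years)
    window = None
    if inc_idx is not None:
        esc_candidates = np.nonzero(dens > config.established)[0]
        esc_candidates = esc_candidates[esc_candidates >= inc_idx]
        if esc_candidates.size:
            esc_idx = int(esc_candidates[0])
            pot_idx = int(np.nonzero(dens > config.potential)[0][0])
            start_idx = max(pot_idx - 1, 0)
            below_pot = dens < config.potential
            dec_idx = _first_run_start(below_pot, config.decline_years, esc_idx + 1)
            if dec_idx is not None:
                end_idx = dec_idx + config.decline_years - 1
                window = OutbreakWindow(
                    start_year=int(years[start_idx]),
                    end_year=int(years[end_idx]),
                    ongoing=False,
                    inception_year=int(years[inc_idx]),
                    escalation_year=int(years[esc_idx]),
                    decline_year=int(years[dec_idx]),
                )
            else:
                window = OutbreakWindow(
                    start_year=int(years[start_idx]),
                    end_year=int(years[-1]),
                    ongoing=True,
                    inception_year=int(years[inc_idx]),
                    escalation_year=int(years[esc_idx]),
                    decline_year=None,
                )
    return SectorOutbreakTimeline(
        sector_id=timeline.sector_id,
        years=years,
        density=dens,
        imputed=timeline.imputed,
        outbreak=window,
    )


def windows_table(timelines: list[SectorOutbreakTimeline]) -> pd.DataFrame:
    """Flatten detected windows into the outbreaks.csv schema."""
    rows = []
    for tl in timelines:
        w = tl.outbreak
        if w is None:
            continue
        rows.append(
            {
                "sector_id": tl.sector_id,
                "start_year": w.start_year,
                "end_year": w.end_year,
                "ongoing": w.ongoing,
                "inception_year": w.inception_year,
                "escalation_year": w.escalation_year,
                "decline_year": w.decline_year if w.decline_year is not None else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sector_id",
            "start_year",
            "end_year",
            "ongoing",
            "inception_year",
            "escalation_year",
            "decline_year",
        ],
    )
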