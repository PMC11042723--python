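"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity with the most literal possible scan so the
production implementations can be checked against code that shares none of
their logic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def oracle_reef_year_density(tows: pd.DataFrame) -> dict:
    """(reef, year) -> (max per-program mean, winning program) by direct loops."""
    out = {}
    for reef in sorted(tows["reef_id"].unique()):
        for year in sorted(tows.loc[tows.reef_id == reef, "year"].unique()):
            best = None
            for program in sorted(
                tows.loc[(tows.reef_id == reef) & (tows.year == year), "program"].unique()
            ):
                sel = tows[
                    (tows.reef_id == reef)
                    & (tows.year == year)
                    & (tows.program == program)
                ]
                mean = sel["cots_count"].mean()
                if best is None or mean > best[0]:
                    best = (mean, program)
            out[(reef, year)] = best
    return out


def oracle_detect_outbreak(years, density, config, uses_established_inception):
    """Literal year-by-year scan of the outbreak-window criteria.

    Returns None or a dict with start/end/ongoing/inception/escalation/decline.
    """
    years = list(years)
    d = list(density)
    n = len(d)
    t_inc = config.established if uses_established_inception else config.potential

    inception = None
    for i in range(n - config.persistence_years + 1):
        if all(d[i + k] > t_inc for k in range(config.persistence_years)):
            inception = i
            break
    if inception is None:
        return None

    escalation = None
    for i in range(inception, n):
        if d[i] > config.established:
            escalation = i
            break
    if escalation is None:
        return None

    first_pot = next(i for i in range(n) if d[i] > config.potential)
    start = max(first_pot - 1, 0)

    decline = None
    for i in range(escalation + 1, n - config.decline_years + 1):
        if all(d[i + k] < config.potential for k in range(config.decline_years)):
            decline = i
            break
    if decline is None:
        return {
            "start_year": years[start],
            "end_year": years[-1],
            "ongoing": True,
            "inception_year": years[inception],
            "escalation_year": years[escalation],
            "decline_year": None,
        }
    return {
        "start_year": years[start],
        "end_year": years[decline + config.decline_years - 1],
        "ongoing": False,
        "inception_year": years[inception],
        "escalation_year": years[escalation],
        "decline_year": years[decline],
    }


def oracle_effort_categories(reefs: pd.DataFrame, threshold: float) -> dict:
    """reef_id -> category by the most literal reading of the stratification."""
    ratios = []
    for _, r in reefs.iterrows():
        if r["max_density"] >= threshold and r["total_hours"] > 0:
            ratios.append(r["total_hours"] / r["max_density"])
    median = float(np.median(ratios)) if ratios else float("nan")
    out = {}
    for _, r in reefs.iterrows():
        if r["max_density"] < threshold:
            out[r["reef_id"]] = "NoOutbreak"
        elif r["total_hours"] <= 0:
            out[r["reef_id"]] = "NoEffort"
        elif r["total_hours"] / r["max_density"] >= median:
            out[r["reef_id"]] = "AboveMedian"
        else:
            out[r["reef_id"]] = "BelowMedian"
    return out
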