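"""Hierarchical Bayesian models and posterior summaries.

Four models serve the sector-level analysis:

* a beta GLMM on tow-level cover midpoints (year cell effects, reef and
  observation-level random intercepts) producing annual sector cover
  estimates;
* a Gaussian mixed model comparing a per-reef response (mean outbreak COTS
  density, or cover change) across sector x outbreak-wave cells with shared
  reef intercepts;
* a penalized cubic-spline smoother (at most four basis functions) for
  relative cover-change trajectories since outbreak onset;
* a Gaussian mixed model of annual cover change across culling-effort
  categories with sector random intercepts.

Every MCMC fit runs 3 chains of 4000 iterations, drops the first 1000 as
burn-in and thins at 5, and reports split-R-hat per parameter; strict mode
raises when any R-hat reaches 1.01.  Posterior summaries are medians with
central 66% and 90% credible intervals and the probability of direction
(posterior mass on the dominant sign).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._samplers import MCMC_DEFAULTS, gibbs_lmm, mh_beta_glmm

logger = logging.getLogger(__name__)

RHAT_LIMIT = 1.01

#: shift used for the log transform of COTS densities (zeros are real data)
DENSITY_LOG_SHIFT = 0.01


class ConvergenceError(RuntimeError):
    """Raised in strict mode when any parameter's R-hat is at or above 1.01."""


@dataclass(frozen=True)
class ModelSpec:
    """Response choice, family, and MCMC settings for a hierarchical fit."""

    response: str = "cots_density"
    family: str = "lognormal_shift"  # or "gaussian"
    mcmc: dict = field(default_factory=lambda: dict(MCMC_DEFAULTS))


@dataclass(frozen=True)
class PosteriorSummary:
    """Median, nested 66%/90% credible intervals, probability of direction."""

    label: str
    median: float
    ci66: tuple
    ci90: tuple
    prob_direction: float
    diagnostics: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "label": self.label,
            "median": self.median,
            "ci66_lo": self.ci66[0],
            "ci66_hi": self.ci66[1],
            "ci90_lo": self.ci90[0],
            "ci90_hi": self.ci90[1],
            "prob_direction": self.prob_direction,
            "rhat_max": self.diagnostics.get("rhat_max", np.nan),
        }


def _rhat(draws: np.ndarray) -> float:
    """Split-R-hat via arviz for draws shaped (chains, draws)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(np.asarray(draws)[:, :, None])
        return float(az.rhat(ds).x.values.max())


def _check_convergence(rhats: dict, strict: bool) -> dict:
    worst = max(rhats.values()) if rhats else np.nan
    ok = bool(worst < RHAT_LIMIT)
    if strict and not ok:
        bad = {k: round(v, 4) for k, v in rhats.items() if v >= RHAT_LIMIT}
        raise ConvergenceError(f"rhat >= {RHAT_LIMIT} for parameters: {bad}")
    if not ok:
        logger.warning("convergence flag: max rhat %.4f", worst)
    return {"rhat": rhats, "rhat_max": float(worst), "converged": ok}


def posterior_summary(
    draws: np.ndarray, label: str = "", diagnostics: dict | None = None
) -> PosteriorSummary:
    """Summarise posterior draws (any shape; flattened across chains)."""
    flat = np.asarray(draws, dtype=float).ravel()
    if flat.size < 500:
        raise ValueError(f"need at least 500 draws, got {flat.size}")
    lo66, med, hi66 = np.quantile(flat, [0.17, 0.5, 0.83])
    lo90, hi90 = np.quantile(flat, [0.05, 0.95])
    p_pos = float(np.mean(flat > 0))
    p_neg = float(np.mean(flat < 0))
    prob_direction = 100.0 * max(p_pos, p_neg, 0.5)
    return PosteriorSummary(
        label=label,
        median=float(med),
        ci66=(float(lo66), float(hi66)),
        ci90=(float(lo90), float(hi90)),
        prob_direction=min(prob_direction, 100.0),
        diagnostics=diagnostics or {},
    )


def fold_change(median_a: float, median_b: float) -> float:
    """Ratio of two posterior medians (e.g. wave-3 over wave-4 density)."""
    if median_b <= 0:
        raise ValueError("fold change undefined for non-positive denominator")
    return median_a / median_b


def compress_unit_interval(y: np.ndarray) -> np.ndarray:
    """Shrink proportions off {0, 1}: y' = (y (n - 1) + 1/2) / n."""
    y = np.asarray(y, dtype=float)
    n = y.size
    return (y * (n - 1) + 0.5) / n


def fit_cover_glmm(
    cover: pd.DataFrame,
    mcmc: dict | None = None,
    seed: int = 0,
    strict: bool = False,
    sector_label: str = "",
) -> pd.DataFrame:
    """Beta GLMM on tow-level cover proportions for a single sector.

    ``cover`` needs columns cover (proportion in [0, 1]), year, reef_id.
    Year is a categorical fixed effect; reef and tow (observation-level)
    random intercepts; logit link.  Returns one row per year with the
    posterior of the population-level annual mean cover (random effects at
    zero).
    """
    y = compress_unit_interval(cover["cover"].to_numpy())
    years = np.sort(cover["year"].unique())
    reefs = np.sort(cover["reef_id"].unique())
    year_index = np.searchsorted(years, cover["year"].to_numpy())
    reef_index = np.searchsorted(reefs, cover["reef_id"].to_numpy())
    draws = mh_beta_glmm(
        y, year_index, reef_index, len(years), len(reefs), mcmc=mcmc, seed=seed
    )
    rhats = {f"a[{yr}]": _rhat(draws["a"][:, :, j]) for j, yr in enumerate(years)}
    rhats["sigma_u"] = _rhat(draws["sigma_u"])
    rhats["phi"] = _rhat(draws["phi"])
    diag = _check_convergence(rhats, strict)
    diag.update(dict(MCMC_DEFAULTS, **(mcmc or {})))
    rows = []
    for j, yr in enumerate(years):
        cover_draws = 1.0 / (1.0 + np.exp(-draws["a"][:, :, j]))
        summ = posterior_summary(cover_draws, f"{sector_label}:{yr}", diag)
        rows.append({"year": int(yr), **summ.as_row()})
    return pd.DataFrame(rows)


def fit_sector_cover_model(
    tows: pd.DataFrame,
    mcmc: dict | None = None,
    seed: int = 0,
    strict: bool = False,
) -> pd.DataFrame:
    """Annual sector-wide cover estimates from tow-level category midpoints.

    Fits :func:`fit_cover_glmm` per sector on the ordinal-category midpoints.
    Because observers report cover on a six-level scale, annual estimates are
    estimates of the mean *midpoint* cover; when a sector's true cover sits
    well inside one category the midpoint itself bounds the attainable
    accuracy.
    """
    from .coral_metrics import category_to_midpoint

    rows = []
    for sector, sub in tows.groupby("sector_id"):
        frame = pd.DataFrame(
            {
                "cover": category_to_midpoint(sub["cover_category"].to_numpy()),
                "year": sub["year"].to_numpy(),
                "reef_id": sub["reef_id"].to_numpy(),
            }
        )
        out = fit_cover_glmm(
            frame, mcmc=mcmc, seed=seed, strict=strict, sector_label=str(sector)
        )
        out.insert(0, "sector_id", sector)
        rows.append(out)
    return pd.concat(rows, ignore_index=True)


def fit_wave_comparison_model(
    values: pd.DataFrame,
    spec: ModelSpec | None = None,
    seed: int = 0,
    strict: bool = False,
) -> dict:
    """Compare a per-reef response across sector x outbreak-wave cells.

    ``values`` needs columns reef_id, sector_id, wave, response.  Reef
    intercepts are shared across waves.  For the ``lognormal_shift`` family
    the response is modelled as log(response + 0.01) and cell summaries are
    back-transformed; contrasts (wave-to-wave within sector) are summarised
    on the model scale, so their probability of direction is the probability
    of a genuine ordering.  Sectors observed in a single wave report the cell
    but no contrast.

    Returns {"cells": [...], "contrasts": [...], "diagnostics": {...}} with
    PosteriorSummary entries.
    """
    spec = spec or ModelSpec()
    df = values.copy()
    if spec.family == "lognormal_shift":
        if (df["response"] < 0).any():
            raise ValueError("negative response under the log family")
        df["y"] = np.log(df["response"] + DENSITY_LOG_SHIFT)
    elif spec.family == "gaussian":
        df["y"] = df["response"].astype(float)
    else:
        raise ValueError(f"unknown family {spec.family!r}")

    cells = (
        df[["sector_id", "wave"]].drop_duplicates().sort_values(["sector_id", "wave"])
    )
    cells = list(cells.itertuples(index=False, name=None))
    cell_of = {c: i for i, c in enumerate(cells)}
    reefs = np.sort(df["reef_id"].unique())
    reef_of = {r: i for i, r in enumerate(reefs)}
    cell_index = df.apply(
        lambda r: cell_of[(r["sector_id"], r["wave"])], axis=1
    ).to_numpy()
    reef_index = df["reef_id"].map(reef_of).to_numpy()

    draws = gibbs_lmm(
        df["y"].to_numpy(),
        cell_index,
        reef_index,
        len(cells),
        len(reefs),
        mcmc=spec.mcmc,
        seed=seed,
    )
    rhats = {
        f"beta[{s}|{w}]": _rhat(draws["beta"][:, :, i])
        for i, (s, w) in enumerate(cells)
    }
    rhats["sigma_u"] = _rhat(draws["sigma_u"])
    rhats["sigma_eps"] = _rhat(draws["sigma_eps"])
    diag = _check_convergence(rhats, strict)
    diag.update(spec.mcmc)

    def back(x):
        if spec.family == "lognormal_shift":
            return np.maximum(np.exp(x) - DENSITY_LOG_SHIFT, 0.0)
        return x

    cell_summaries = [
        posterior_summary(back(draws["beta"][:, :, i]), f"{s}|wave{w}", diag)
        for i, (s, w) in enumerate(cells)
    ]

    contrasts = []
    for sector in sorted({s for s, _ in cells}):
        waves = sorted(w for s, w in cells if s == sector)
        if len(waves) < 2:
            logger.info(
                "sector %s observed in a single wave; contrast omitted", sector
            )
            continue
        w_lo, w_hi = waves[0], waves[-1]
        diff = (
            draws["beta"][:, :, cell_of[(sector, w_lo)]]
            - draws["beta"][:, :, cell_of[(sector, w_hi)]]
        )
        contrasts.append(
            posterior_summary(diff, f"{sector}:wave{w_lo}-wave{w_hi}", diag)
        )
    return {"cells": cell_summaries, "contrasts": contrasts, "diagnostics": diag}


def filter_outbreak_reefs(
    values: pd.DataFrame, reef_max_density: dict, threshold: float
) -> pd.DataFrame:
    """Keep reefs whose maximum recorded density ever exceeded the threshold."""
    keep = values["reef_id"].map(
        lambda r: reef_max_density.get(r, 0.0) > threshold
    )
    return values.loc[keep].reset_index(drop=True)


def fit_trajectory_smoother(
    trajectories: pd.DataFrame,
    grouping: str = "sector_id",
    horizon_years: int = 6,
    min_points: int = 5,
) -> pd.DataFrame:
    """Penalized cubic-spline fit of relative cover change vs years since onset.

    One smooth per group (sector or management action), gaussian response,
    basis dimension four; the penalty weight is chosen by generalized
    cross-validation.  Returns fitted mean and 95% confidence band on the
    annual grid 0..horizon (truncated to each group's observed span).
    """
    from statsmodels.gam.api import BSplines, GLMGam

    rows = []
    for group, sub in trajectories.groupby(grouping):
        x = sub["years_since_onset"].to_numpy(dtype=float)
        yv = sub["relative_change_pct"].to_numpy(dtype=float)
        if len(sub) < min_points or np.unique(x).size < 4:
            logger.warning("group %s: insufficient points for smoother", group)
            continue
        if np.ptp(yv) == 0:  # constant response: spline is the constant itself
            grid = np.arange(0, min(horizon_years, int(x.max())) + 1)
            for g in grid:
                rows.append(
                    {"group": group, "years_since_onset": int(g),
                     "fit": float(yv[0]), "ci95_lo": float(yv[0]),
                     "ci95_hi": float(yv[0])}
                )
            continue
        bs = BSplines(x[:, None], df=[4], degree=[3], include_intercept=True)
        model = GLMGam(yv, exog=np.ones((len(yv), 1)), smoother=bs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                alpha = model.select_penweight()[0]
                res = GLMGam(
                    yv, exog=np.ones((len(yv), 1)), smoother=bs, alpha=alpha
                ).fit()
            except Exception:  # GCV can fail on tiny groups; fall back unpenalized
                res = model.fit()
            grid = np.arange(0, min(horizon_years, int(x.max())) + 1, dtype=float)
            pred = res.get_prediction(
                exog=np.ones((len(grid), 1)), exog_smooth=grid[:, None]
            )
            ci = pred.conf_int()
        for g, m, lo, hi in zip(grid, pred.predicted_mean, ci[:, 0], ci[:, 1]):
            rows.append(
                {
                    "group": group,
                    "years_since_onset": int(g),
                    "fit": float(m),
                    "ci95_lo": float(lo),
                    "ci95_hi": float(hi),
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "years_since_onset", "fit", "ci95_lo", "ci95_hi"]
    )


def fit_effort_model(
    changes: pd.DataFrame,
    mcmc: dict | None = None,
    seed: int = 0,
    strict: bool = False,
) -> dict:
    """Annual cover change (pp/yr) across culling-effort categories.

    ``changes`` needs columns annual_pp_per_year, category, sector_id.
    Gaussian response, category cell means, sector random intercepts.
    Returns {"categories": {name: PosteriorSummary}, "diagnostics": {...}}.
    """
    df = changes.copy()
    cats = sorted(df["category"].unique())
    sectors = sorted(df["sector_id"].unique())
    for cat in cats:
        n = int((df["category"] == cat).sum())
        if n < 2:
            logger.warning(
                "effort category %s has %d reef(s); interval will be wide", cat, n
            )
    cat_index = df["category"].map({c: i for i, c in enumerate(cats)}).to_numpy()
    sec_index = df["sector_id"].map({s: i for i, s in enumerate(sectors)}).to_numpy()
    draws = gibbs_lmm(
        df["annual_pp_per_year"].to_numpy(),
        cat_index,
        sec_index,
        len(cats),
        len(sectors),
        mcmc=mcmc,
        seed=seed,
    )
    rhats = {f"beta[{c}]": _rhat(draws["beta"][:, :, i]) for i, c in enumerate(cats)}
    rhats["sigma_u"] = _rhat(draws["sigma_u"])
    rhats["sigma_eps"] = _rhat(draws["sigma_eps"])
    diag = _check_convergence(rhats, strict)
    diag.update(dict(MCMC_DEFAULTS, **(mcmc or {})))
    summaries = {
        c: posterior_summary(draws["beta"][:, :, i], c, diag)
        for i, c in enumerate(cats)
    }
    return {"categories": summaries, "diagnostics": diag}
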