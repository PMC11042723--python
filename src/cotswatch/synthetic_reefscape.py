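"""Synthetic reefscape generator: coupled predator-coral dynamics plus an
observation model matching the manta-tow data schema.

The generator emulates the structure the surveillance analysis assumes: a
COTS outbreak wave seeded in the first sector propagates to later sectors
with a fixed lag, densities grow multiplicatively until coral prey is
depleted, coral follows logistic growth (about +1 percentage point per year
at moderate cover) minus density-proportional predation and any scheduled
episodic disturbance, and culling removes density in proportion to diver
bottom-hours.  Observation is tow-level: Poisson COTS counts per ~2000 m^2
tow and ordinal cover categories with additive observer noise.

Scenario presets (limited / reactive / timely / proactive) differ only in
when culling starts relative to the observed sector threshold crossings and
in how much effort is allocated.  Preset policies key on the *observed*
sector densities — the same aggregates the downstream pipeline recomputes —
mirroring how managers act on survey data rather than on the unobservable
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .coral_metrics import DEFAULT_SCHEME, CategoryScheme
from .surveillance_io import Registry, ThresholdConfig

PRESETS = ("limited", "reactive", "timely", "proactive")

# fixed stream tags so post-hoc observation reproduces in-loop observation
_OBS_STREAM = 7


@dataclass(frozen=True)
class SimulationConfig:
    """Reefscape dynamics, intervention, and observation parameters.

    Rates are annual.  ``r_coral`` and ``K`` are calibrated so undisturbed
    coral gains about one percentage point of cover per year at moderate
    cover.  ``predation_coeff`` is the relative cover loss per unit COTS
    density per year; ``cull_efficiency`` is the density removed per 100
    diver-hours at a reef.  The outbreak wave is seeded in sector 1 at
    ``first_onset_offset`` years into the series and reaches sector s after
    ``wave_lag_years * (s - 1)`` further years.
    """

    n_sectors: int = 4
    reefs_per_sector: int = 10
    years: tuple = (2010, 2024)  # inclusive span
    wave_lag_years: int = 2
    first_onset_offset: int = 2
    r_coral: float = 0.06
    K: float = 0.8
    predation_coeff: float = 0.15
    cots_growth: float = 2.5
    cots_collapse_cover: float = 0.08
    collapse_factor: float = 0.15
    density_cap: float = 3.0
    seed_density: float = 0.04
    baseline_density: float = 0.01
    cull_efficiency: float = 0.5
    disturbance_schedule: tuple = ()  # (year, (sector ids), mortality fraction)
    tows_per_reef: int = 40
    detection_scale: float = 1.0
    cover_noise_sd: float = 0.03
    init_cover_range: tuple = (0.22, 0.32)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.K <= 1):
            raise ValueError("carrying capacity K must be in (0, 1]")
        for name in (
            "r_coral",
            "predation_coeff",
            "cots_growth",
            "cull_efficiency",
            "detection_scale",
            "cover_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def sector_ids(self) -> list[str]:
        return [f"SEC{s}" for s in range(1, self.n_sectors + 1)]

    def reef_ids(self, sector_index: int) -> list[str]:
        return [
            f"S{sector_index}R{r:02d}" for r in range(1, self.reefs_per_sector + 1)
        ]

    def onset_year(self, sector_index: int) -> int:
        return (
            self.years[0]
            + self.first_onset_offset
            + self.wave_lag_years * (sector_index - 1)
        )

    def registry(
        self, uses_established_inception: dict | None = None
    ) -> Registry:
        flags = uses_established_inception or {}
        rows = []
        for s in range(1, self.n_sectors + 1):
            sector = f"SEC{s}"
            for reef in self.reef_ids(s):
                rows.append(
                    {
                        "reef_id": reef,
                        "sector_id": sector,
                        "sector_order": s,
                        "uses_established_inception": bool(flags.get(sector, False)),
                    }
                )
        return Registry(table=pd.DataFrame(rows))


def apply_culling(density: float, hours: float, config: SimulationConfig) -> float:
    """Density remaining after culling: linear removal per 100 diver-hours."""
    if density < 0 or hours < 0:
        raise ValueError("density and hours must be non-negative")
    return max(0.0, density - config.cull_efficiency * hours / 100.0)


def _reef_obs_rng(config: SimulationConfig, sector_index: int, reef_index: int, year: int):
    """Per reef-year observation stream, independent of simulation order."""
    ss = np.random.SeedSequence(
        [config.seed, _OBS_STREAM, sector_index, reef_index, year]
    )
    return np.random.default_rng(ss)


def _observe_reef_year(
    config: SimulationConfig,
    sector_index: int,
    reef_index: int,
    year: int,
    true_density: float,
    true_cover: float,
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    rng = _reef_obs_rng(config, sector_index, reef_index, year)
    n = config.tows_per_reef
    counts = rng.poisson(config.detection_scale * true_density, size=n)
    noisy = np.clip(
        true_cover + rng.normal(0.0, config.cover_noise_sd, size=n), 0.0, 1.0
    )
    cats = scheme.to_category(noisy)
    return pd.DataFrame(
        {
            "reef_id": config.reef_ids(sector_index)[reef_index],
            "sector_id": f"SEC{sector_index}",
            "year": year,
            "program": "LTMP",
            "tow_index": np.arange(1, n + 1),
            "cover_category": cats,
            "cots_count": counts,
        }
    )


class CullPolicy:
    """Closed-loop culling policy: decides hours per reef from observations.

    Subclasses receive, each year, the observed per-reef mean COTS densities
    (the same statistic the pipeline computes from the emitted tows) and
    return diver bottom-hours per reef.
    """

    def hours(self, year, sector_index, obs_sector_mean, obs_reef_density, config):
        raise NotImplementedError


class NoCullPolicy(CullPolicy):
    def hours(self, year, sector_index, obs_sector_mean, obs_reef_density, config):
        return {reef: 0.0 for reef in obs_reef_density}


class ThresholdCullPolicy(CullPolicy):
    """Activate a sector when its observed mean density crosses a trigger;
    thereafter cull every reef whose observed density exceeds a floor,
    removing ``removal_frac`` of the observed density (an optional per-year
    hour budget caps the allocation)."""

    def __init__(
        self,
        trigger: float,
        removal_frac: float,
        reef_floor: float = 0.02,
        sector_year_budget: float | None = None,
    ) -> None:
        self.trigger = trigger
        self.removal_frac = removal_frac
        self.reef_floor = reef_floor
        self.sector_year_budget = sector_year_budget
        self._active: set = set()

    def hours(self, year, sector_index, obs_sector_mean, obs_reef_density, config):
        if obs_sector_mean > self.trigger:
            self._active.add(sector_index)
        out = {reef: 0.0 for reef in obs_reef_density}
        if sector_index not in self._active:
            return out
        for reef, dens in obs_reef_density.items():
            if dens > self.reef_floor:
                out[reef] = self.removal_frac * dens * 100.0 / config.cull_efficiency
        total = sum(out.values())
        if self.sector_year_budget is not None and total > self.sector_year_budget:
            scale = self.sector_year_budget / total
            out = {reef: h * scale for reef, h in out.items()}
        return out


@dataclass
class ScenarioBundle:
    """Everything a scenario emits: truth plus the observed datasets."""

    preset: str
    config: SimulationConfig
    truth: pd.DataFrame
    tows: pd.DataFrame
    culls: pd.DataFrame
    registry: Registry

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tows": out_dir / "tows.csv",
            "culls": out_dir / "culls.csv",
            "registry": out_dir / "registry.csv",
            "truth": out_dir / "truth.csv",
        }
        self.tows.to_csv(paths["tows"], index=False)
        self.culls.to_csv(paths["culls"], index=False)
        self.registry.to_csv(paths["registry"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def simulate_truth(
    config: SimulationConfig, policy: CullPolicy | None = None
) -> pd.DataFrame:
    """Run the coupled predator-coral dynamics; fully deterministic given seed.

    Returns one row per (reef, year) with ``true_cover`` and ``true_density``
    at the start of the year (pre-cull, what surveys see) and the
    ``applied_hours`` of culling.  The annual update order is: observe ->
    cull -> coral growth minus predation and disturbance -> density growth or
    collapse into the next year.
    """
    policy = policy or NoCullPolicy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    years = config.year_list
    disturbance = {}
    for year, sectors, mortality in config.disturbance_schedule:
        for sec in sectors:
            disturbance[(year, sec)] = float(mortality)

    cover: dict[str, float] = {}
    density: dict[str, float] = {}
    reef_sector: dict[str, int] = {}
    for s in range(1, config.n_sectors + 1):
        for reef in config.reef_ids(s):
            cover[reef] = float(rng.uniform(*config.init_cover_range))
            density[reef] = config.baseline_density
            reef_sector[reef] = s

    rows = []
    for year in years:
        # wave seeding at each sector's onset year
        for reef, s in reef_sector.items():
            if year == config.onset_year(s):
                density[reef] = max(density[reef], config.seed_density)

        hours_this_year: dict[str, float] = {}
        for s in range(1, config.n_sectors + 1):
            reefs = config.reef_ids(s)
            obs_reef = {}
            for i, reef in enumerate(reefs):
                obs_rng = _reef_obs_rng(config, s, i, year)
                counts = obs_rng.poisson(
                    config.detection_scale * density[reef], size=config.tows_per_reef
                )
                obs_reef[reef] = float(np.mean(counts))
            obs_sector = float(np.mean(list(obs_reef.values())))
            hours_this_year.update(
                policy.hours(year, s, obs_sector, obs_reef, config)
            )

        for reef, s in reef_sector.items():
            d_pre = density[reef]
            c = cover[reef]
            rows.append(
                {
                    "reef_id": reef,
                    "sector_id": f"SEC{s}",
                    "year": year,
                    "true_cover": c,
                    "true_density": d_pre,
                    "applied_hours": hours_this_year.get(reef, 0.0),
                }
            )
            d_post = apply_culling(d_pre, hours_this_year.get(reef, 0.0), config)
            mort = disturbance.get((year, f"SEC{s}"), 0.0)
            c_next = (
                c
                + config.r_coral * c * (1.0 - c / config.K)
                - config.predation_coeff * d_post * c
                - mort * c
            )
            c_next = float(np.clip(c_next, 0.0, config.K))
            if not np.isfinite(c_next) or not np.isfinite(d_post):
                raise FloatingPointError(
                    f"non-finite state at reef {reef}, year {year}"
                )
            if year < config.onset_year(s):
                # endemic background population before the wave arrives
                d_next = min(d_post, config.baseline_density)
            elif c_next < config.cots_collapse_cover:
                d_next = d_post * config.collapse_factor
            else:
                d_next = d_post * config.cots_growth
            density[reef] = min(max(d_next, 0.0), config.density_cap)
            cover[reef] = c_next
    return pd.DataFrame(rows)


def observe_tows(
    truth: pd.DataFrame,
    config: SimulationConfig,
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Tow-level observations of a truth table.

    Counts are Poisson around ``detection_scale * true_density``; cover gets
    additive observer noise before ordinal binning.  The per reef-year random
    stream depends only on (seed, reef, year), so observations agree exactly
    with those seen by a closed-loop policy during simulation.
    """
    frames = []
    for row in truth.itertuples(index=False):
        s = int(str(row.sector_id).removeprefix("SEC"))
        reef_index = config.reef_ids(s).index(row.reef_id)
        frames.append(
            _observe_reef_year(
                config,
                s,
                reef_index,
                int(row.year),
                float(row.true_density),
                float(row.true_cover),
                scheme,
            )
        )
    return pd.concat(frames, ignore_index=True)


def _preset_policy(preset: str, thresholds: ThresholdConfig) -> CullPolicy:
    if preset == "proactive":
        return ThresholdCullPolicy(trigger=0.03, removal_frac=0.9)
    if preset == "timely":
        return ThresholdCullPolicy(trigger=thresholds.potential, removal_frac=0.9)
    if preset == "reactive":
        return ThresholdCullPolicy(trigger=0.35, removal_frac=0.35)
    raise ValueError(f"unknown preset: {preset!r}")


def _cull_table(truth: pd.DataFrame) -> pd.DataFrame:
    culls = truth.loc[truth["applied_hours"] > 0, ["reef_id", "year", "applied_hours"]]
    culls = culls.rename(columns={"applied_hours": "hours"})
    return culls.sort_values(["reef_id", "year"]).reset_index(drop=True)


def generate_scenario(
    preset: str,
    seed: int,
    config: SimulationConfig | None = None,
    thresholds: ThresholdConfig | None = None,
    out_dir: str | Path | None = None,
) -> ScenarioBundle:
    """Generate the observed datasets plus ground truth for a named preset.

    Presets differ only in the culling schedule: ``proactive`` starts before
    the potential-threshold crossing, ``timely`` at the crossing with
    sufficient sustained effort, ``reactive`` later with insufficient effort,
    and ``limited`` starts at the severe crossing with a total budget under
    10% of the timely schedule's hours at the same seed.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose one of {PRESETS}")
    thresholds = thresholds or ThresholdConfig()
    config = replace(config or SimulationConfig(), seed=seed)

    if preset == "limited":
        timely_truth = simulate_truth(config, _preset_policy("timely", thresholds))
        timely_total = float(timely_truth["applied_hours"].sum())
        n_years = len(config.year_list)
        # spread <10% of the timely budget over the post-severe years
        budget_per_sector_year = 0.08 * timely_total / (config.n_sectors * max(n_years - 6, 1))
        policy: CullPolicy = ThresholdCullPolicy(
            trigger=thresholds.severe,
            removal_frac=0.9,
            sector_year_budget=budget_per_sector_year,
        )
    else:
        policy = _preset_policy(preset, thresholds)

    truth = simulate_truth(config, policy)
    tows = observe_tows(truth, config)
    bundle = ScenarioBundle(
        preset=preset,
        config=config,
        truth=truth,
        tows=tows,
        culls=_cull_table(truth),
        registry=config.registry(),
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
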