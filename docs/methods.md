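# Methods

This note records the models, conventions and numerical choices behind
`cotswatch`, and what the synthetic experiments do and do not demonstrate.

## Data model and density aggregation

A tow record is one two-minute manta tow (~2000 m²): an ordinal hard-coral
cover category (0, 1–10, 11–30, 31–50, 51–75, 76–100 %) and a COTS count.
Cover categories are converted to midpoints (0, 0.055, 0.205, 0.405, 0.63,
0.88 as proportions) for all quantitative work. Reef-year COTS density is
the mean count per tow within a program; when several programs survey a
reef in one year the **maximum** per-program mean is taken, because
pre-cull surveys by field-management and control programs can catch
densities that annual monitoring misses. Sector series are unweighted means
of reef densities (weighting by tow count is available but off by
default); interior missing years are linearly interpolated and flagged,
leading/trailing gaps are never extrapolated.

## Outbreak periods

Density thresholds: potential > 0.11, established > 0.22, severe ≥ 1.0
COTS/tow. All crossings are strict except the severe boundary, which is
inclusive. A sector-wide outbreak window requires

1. *inception*: the first year of ≥ 2 consecutive years above the inception
   threshold (the potential threshold, or the established threshold for
   sectors flagged in the registry as historically high-magnitude);
2. *escalation*: a year at or after inception above the established
   threshold.

The window opens one year before the first potential crossing (clipped to
the observed span when the series already starts above threshold, so that
window years remain a subset of observed years) and closes with the two
consecutive sub-potential years, which are counted inside the window; with
no such run the outbreak is ongoing through the last observed year.
Persistence is read as *consecutive* years — the stricter, testable
interpretation. Both the closing convention and the persistence/decline
run lengths are configurable. The detector is verified against an
exhaustive criterion-scanning oracle on 10,000 random series.

## Management actions and effort strata

Let `y_cull` be the first year with positive cull hours, `y_pot`/`y_sev`
the first observed crossings of the potential/severe thresholds.

- **NoAction**: no hours at all.
- **Proactive**: `y_cull < y_pot` (including the case where the crossing
  never happens).
- Otherwise a **suppression test** decides between Timely and the rest:
  after `y_cull` the sector density must fall below the potential threshold
  for a sustained run (the decline-run length), *and* coral cover at the
  end of the outbreak window must be at least `1 − depletion_fraction`
  (default 75%) of the cover at its start. The second clause separates
  management suppression from prey-depletion collapse, in which densities
  also fall but only after the coral is eaten out. When suppression
  prevented a window from ever forming, the cover check uses the span from
  one year before the potential crossing to the end of the sub-threshold
  run.
- **Timely**: `y_pot ≤ y_cull` and suppression achieved.
- **Reactive**: culling started before the severe crossing but suppression
  failed.
- **Limited**: culling started at or after the severe crossing (or effort
  was otherwise insufficient).

Every label carries a `rationale` string tracing the criterion years and
the cover window used, for audit.

Reef effort strata use the ratio total hours / max COTS density over the
reef's sector outbreak window. Reefs under the reef outbreak threshold
(default 0.11 COTS/tow; the published effort analysis quotes 0.1 — the
default keeps the single threshold and is configurable) form the
NoOutbreak control group; outbreak reefs with zero hours are NoEffort; the
remainder split at the **median ratio computed over outbreak reefs with
positive hours** (including zero-effort reefs would drag the median to
zero and merge the strata). Ties at the median go AboveMedian. Effort
shares are percentages of the summed sector hours, rounded half-up to one
decimal.

## Change metrics

Relative change is percent of the baseline cover, `100·(end−start)/start`;
annual absolute change is percentage points per year,
`100·(end−start)/duration`. Only this pairing makes per-wave relative
changes and per-year rates mutually consistent. Start/end covers are raw
tow-mean midpoints at the surveys nearest inside the window; the
model-based annual estimate is reserved for sector summaries. Post-onset
trajectories take the baseline from the window start year or the nearest
prior survey; reefs with no baseline are excluded (logged) and reefs with
fewer than three surveys in the horizon are flagged sparse.

## Hierarchical models

All MCMC fits run 3 chains × 4000 iterations, discard the first 1000 as
burn-in and thin at 5 (1800 retained draws), and report split-R-hat per
parameter (via arviz). Posterior summaries are medians, central 66% and
90% quantile intervals, and the probability of direction (posterior mass
on the dominant sign, 50–100%). Strict mode raises if any parameter's
R-hat reaches 1.01; it is off by default (see Limitations).

**Annual sector cover** — beta GLMM on tow midpoints: logit(μ) = year cell
effect + reef intercept + tow-level (observation) intercept, response
Beta(μφ, (1−μ)φ). Midpoints are compressed off the closed interval by
`y′ = (y(n−1)+½)/n` so category 0 is admissible. Year effects get normal(0,
2.5²) priors on the logit scale; random-effect variances get inverse-gamma
priors; φ gets a Gamma(2, rate 0.05) prior. The sampler is an adaptive
Metropolis-within-Gibbs: year, reef and observation blocks factorise over
the data and are proposed and accepted element-wise in vectorised sweeps,
variances are conjugate draws, and two likelihood-invariant "location
swap" moves (shift all year effects by δ against the reef, resp.
observation, intercepts) break the additive ridge that otherwise stalls
mixing of the reported year effects. The annual estimate is the
population-level mean cover (random effects at zero).

**Wave and effort comparisons** — Gaussian linear mixed models with a
cell-means fixed design (sector × wave, or effort category) and one
grouped random intercept (reef shared across waves, or sector). The
response is standardized internally; fixed effects get normal(0, 2.5²)
priors on that scale. Estimation is blocked Gibbs with the full
coefficient vector drawn jointly from its multivariate-normal conditional
(removing the cell/intercept ridge) and conjugate inverse-gamma variance
draws — the conjugacy is why inverse-gamma was preferred over half-normal
priors on the standard deviations; at these settings the sampler converges
essentially immediately (R-hat ≈ 1.00). COTS density is modelled as
normal on log(density + 0.01) with back-transformed cell summaries (the
family is configurable; identity-normal is available); wave-to-wave
contrasts are summarised on the model scale, and fold changes are ratios
of back-transformed cell medians. Only reefs whose density ever exceeded
the potential threshold enter the wave comparisons
(`filter_outbreak_reefs`). Sectors observed in a single wave report their
cell but no contrast.

**Trajectory smoother** — per group (sector or action), a penalized cubic
B-spline with basis dimension four and gaussian response, penalty weight
chosen by generalized cross-validation (statsmodels `GLMGam`; unpenalized
fallback when GCV fails on tiny groups), evaluated with 95% confidence
bands on the annual grid 0–6 years since onset (truncated to the observed
span). Groups with fewer than five points, fewer than four distinct years,
or zero response variance are handled separately (skipped with a warning,
or returned as the exact constant).

## The synthetic reefscape

The generator emulates the structure the analysis assumes, not any
particular reef system. Discrete annual steps; within-reef tows are pure
observation replicates. Defaults: 4 sectors × 10 reefs × 15 years, 40 tows
per reef-year.

- *Coral*: logistic growth `r·c·(1−c/K)` with r = 0.06/yr and K = 0.8,
  giving ≈ +1 pp/yr at 0.2–0.3 cover — the observed growth rate of reefs
  free of COTS pressure; minus predation `0.15·density·c` per year, minus
  any scheduled disturbance mortality.
- *COTS wave*: seeded at 0.04 COTS/tow in sector 1 two years into the
  series, reaching sector *s* after `2·(s−1)` further years; grows ×2.5 per
  year, capped at 3 COTS/tow; collapses (×0.15 per year) when local cover
  falls below 0.08 — prey depletion ends unmanaged outbreaks. Background
  density before the wave is 0.01.
- *Culling*: density removed = `0.5 × hours/100` per reef, linear in hours
  (no dose–response is published; linearity is the simplest testable
  contract), applied after the year's surveys and before predation.
- *Observation*: counts are Poisson(density) per tow; cover gets additive
  normal observer noise (SD 0.03), truncated to [0, 1], then binned to the
  six categories. The random stream is addressed by (seed, reef, year), so
  post-hoc observation reproduces exactly what a closed-loop policy saw
  during simulation.

Scenario presets are closed-loop policies keyed on the *observed* sector
mean density — the same statistic the pipeline recomputes — which makes
the generated cull-start years consistent with the detected crossings by
construction, as they are for real managers acting on survey data.
Proactive triggers at 0.03 (below the potential threshold) and removes 90%
of observed density; Timely triggers at the potential threshold with the
same removal; Reactive triggers at 0.35 but removes only 35% (insufficient
against ×2.5 growth); Limited triggers at the severe threshold with a
total budget fixed at 8% of the same-seed Timely schedule. These settings
were chosen once to realise the four management archetypes and are not
fitted to any data.

What passing tests show: the pipeline recovers the generating regime
(labels, windows, folds, rates) from data with realistic observation noise
and the assumed dynamics. What they do not show: performance under model
misspecification — real reefs have larval connectivity, spatially
structured tows, disturbance attribution problems and observer effects the
generator does not emulate.

## Numerical choices and degenerate inputs

- Ordinal-cover responses are compressed off {0, 1} before beta fitting.
- Zero starting cover makes relative change undefined: the reef is excluded
  with a logged reason. Zero max density routes a reef to NoOutbreak before
  any effort ratio is computed. Zero total hours across all sectors makes
  effort shares a hard error.
- Sector series shorter than three years (or the persistence run) are a
  hard error for outbreak detection.
- `posterior_summary` requires ≥ 500 draws.
- Report-table shares use decimal half-up rounding to one decimal, so the
  seven-sector shares sum to 100 ± 0.3.
- All randomness flows from `numpy.random.SeedSequence`; equal seeds give
  byte-identical simulator output and identical posterior summaries.

## Known limitations

- **Ordinal coarsening.** Annual cover estimates are estimates of the mean
  *category midpoint*. When a sector's true cover sits well inside one
  category, the estimate is attracted to that bin's midpoint and no amount
  of data removes the residual bias; interval calibration of the
  hierarchical machinery is therefore demonstrated on continuous beta
  responses (`fit_cover_glmm`), while the category path adds the
  measurement coarsening on top.
- **Beta-GLMM variance split.** The tow-level intercept variance and the
  beta precision φ both absorb overdispersion and are only weakly
  identified; their R-hat can exceed 1.01 at the mandated settings while
  the reported year effects converge (R-hat ≈ 1.00). All R-hats are
  reported; strict mode gates on all of them and is therefore opt-in.
- **Suppression proxy.** The cover-retention clause uses a fixed
  depletion fraction (default 25%) as the boundary between suppression and
  prey depletion; sectors near that boundary are sensitive to it.
- The simulator's culling dose–response is linear and its wave propagation
  deterministic; both are conventions, not estimates of any reef system's
  parameters.
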