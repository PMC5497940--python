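# Methods

## Scope and model structure

The engine computes, for every scored unit (ten goals, four of them split
into subgoals) in every region: current status `x` (0–100 against a
reference point), proportional five-year trend `T` (clamped to [−1, 1]),
aggregate pressure `p` and resilience `r` (both 0–1), the likely future
status `x_F = x(1+δ)[1 + βT + (1−β)(r−p)]` clamped to [0, 100], and the
score `(x + x_F)/2`. Subgoals average into parents, goals into a region
Index, regions into a global score (unweighted or EEZ-area-weighted). All
internal dimensionless quantities live on [0, 1]; the 0–100 scale appears
only at the output boundary.

Three goals whose internal models depend on discontinued or purely
proprietary sources (tourism & recreation, mariculture, livelihoods &
economies) consume a precomputed status layer directly.

### Parameters

| parameter | default | meaning |
|---|---|---|
| β | 0.67 | weight of trend vs. (r − p) in likely future status |
| δ | 0.0 | future-status discount rate |
| γ | 0.5 | weight of ecological vs. social pressure |
| goal / subgoal weights | equal | aggregation weights |
| trend clamp | ±1 | keeps the multiplicative future-status model bounded |
| LSP reference fraction | 0.30 | protected share of the coastal zone scoring 100 |

β, γ and δ follow the published index framework and are exposed in
`EngineConfig` rather than hard-coded, since reasonable assessments may
weight near-term trend differently.

## Goal models

**Fisheries.** Stock condition is B/B_MSY. The catch-only estimator draws
`n_draws` (r, K) pairs log-uniformly (r ∈ [0.05, 1.0], K ∈ [1, 100] × max
catch), an initial depletion B0/K uniformly, runs Schaefer dynamics forward
through the observed catch, and keeps draws whose biomass stays above
K/1000 and whose final depletion lands in a prior window; the per-year
estimate is the median of 2B/K over kept draws. The final-depletion window
is the method's information carrier — catch-only data cannot identify
terminal state without it (with any fixed window the estimate degenerates
to the window midpoint regardless of the data, and even anti-correlates
with truth because the K prior scales with maximum catch). We therefore
condition it on the catch trajectory, as the standard implementations do,
but continuously rather than in three bins: a fishery whose 3-year-smoothed
catch still peaks at the end of the series is treated as developing
(window [0.4, 0.8], the standard bin); a post-peak fishery gets a window of
half-width 0.2 centred at 0.5 × (recent catch / smoothed peak), the
constant-exploitation-rate reading under which catch tracks biomass. Fixed
windows remain available in `CatchMsyConfig`. Assessment-database values
override catch-only estimates per (stock, year).

Scoring: `stock_score` is 1 on B/B_MSY ∈ [0.95, 1.05], ramps linearly from
0 below 0.95, and declines linearly to a floor of 0.25 at B/B_MSY = 3 —
both over- and under-exploitation are penalised, under-exploitation less
severely. Regional status is the catch-weighted geometric mean (weights =
mean catch over available years) of stock scores × taxonomic penalty
(levels 1–6 → 0.1, 0.25, 0.5, 0.8, 0.9, 1.0; only the "miscellaneous"
level-1 value of 0.1 is a fixed convention, the interior values interpolate
monotonically and are configurable).

**Natural products.** Per product: 5-year *trailing* running mean of
harvest (no lookahead in a yearly-updated indicator); reference = 65% of
the running-mean's historical (expanding) peak; score = smoothed current /
reference, capped at 1; products with fewer than 4 data years are dropped;
the fish-oil score is multiplied by the region's fisheries score/100 as its
sustainability term. Regional status is the peak-harvest-weighted mean over
retained products — peak magnitude proxies a product's importance in the
absence of value data.

**Lasting special places.** status = 100 × min(1, protected fraction /
0.30) of the coastal zone, the zone area supplied directly as a layer.

**Species / iconic species.** Risk-category weights LC…EX = 0, 0.2, 0.4,
0.6, 0.8, 1.0; status = 100 × max(0, ((1 − mean weight) − 0.25)/0.75), i.e.
a region scores 0 once its species average 75% of the way to extinction.
The iconic trend comes from a linear model of mean risk weight over the ten
most recent years, mapped through the status formula and converted to the
proportional convention (the legacy categorical ±0.5 trend is not used).

**Habitats / coastal protection / carbon storage.** Habitat health =
min(1, condition/reference). The habitat subgoal averages health across
habitats; coastal protection and carbon storage weight it by service rank ×
extent (protection ranks: sea ice, mangrove, coral 4; salt marsh 3;
seagrass 1; carbon ranks: the three vegetated habitats, equal).

**Artisanal opportunity.** status = 100 × (1 − min(1, need/q95)), the
cross-region 95th quantile replacing the maximum so a single outlier does
not own the reference.

**Clean waters.** status = 100 × geometric mean of (1 − component) over
the four contamination components; one fully contaminated component forces
zero.

**Trend.** OLS slope over the ≤5 most recent status years × 5 ÷ status at
the earliest year used, clamped to [−1, 1]; a zero earliest status makes
the proportional change undefined and is flagged and treated as 0.

## Pressures and resilience

Gridded inputs are abstract cells (cell_id, region, area, coastal flag);
every published operation on rasters reduces to per-cell series plus
area-weighted region means, so no geographic coordinates are carried.

- **Ocean acidification**: cell pressure = (Ω_base − Ω_year)/(Ω_base − 1)
  clamped to [0, 1]; Ω_year ≤ 1 (undersaturation) ⇒ 1; improvement ⇒ 0;
  cells whose baseline is itself ≤ 1 while current Ω is above it are
  indeterminate under this scaling and excluded with a warning.
- **Sea level rise**: coastal cells only; annual mean of monthly anomalies
  floored at 0, rescaled by the maximum annual cell anomaly in the
  reference window (default: five most recent years). Annual aggregation
  uses the mean of months (the alternative, max, is stricter but noisier).
- **UV / SST**: a week is anomalous above the cell's full-series mean + 1
  SD (the climatology window is the whole series; nothing shorter is
  defensible for a 6–12-year record), at most 52 events per year; pressure
  = trailing 5-year event sum / 99.99th quantile of all 5-year sums across
  cells and windows, capped at 1. The quantile reference is computed
  empirically from the run's own input and stored with the output
  (`DataFrame.attrs["reference"]`), so a rerun is reproducible even as data
  grow.
- **Fishing**: cell catch / net primary productivity; industrial catch
  split into high/low-bycatch by the regional gear proportion; artisanal
  (+ subsistence + recreational) kept as its own low-bycatch layer; each
  layer rescaled by its own 99.99th quantile.
- **Social**: SPI = mean of 3 dimension means of 4 components each.
  Missing components are imputed by regressing the component on the mean of
  the region's observed components, fit on regions that carry the needed
  columns (falling back to partial overlap when few regions are complete) —
  a single-predictor model chosen because the all-components regression is
  underdetermined at realistic missingness; it is exact whenever components
  are affine in a common latent signal. Regions with no components at all
  are predicted from UN georegion indicators + WGI (indicators without
  support among scored regions are dropped). Uninhabited regions receive no
  social score. Social pressure = 1 − SPI/100 (and 1 − WGI); social
  resilience = SPI/100 (and WGI).

Aggregation: within each ecological category, member layers combine by
rank-weighted mean (ranks 1–3); ecological pressure is the mean over
categories with at least one layer; `p = γ·p_ecol + (1−γ)·p_social`.
Resilience: regulatory layers average within the ecological category they
address, then across categories; r = equal-weight mean of the regulatory,
ecological-integrity and social components present. Layers missing for a
region are dropped with reweighting and a logged warning — never treated as
silent zeros. Uninhabited regions omit the social term with renormalisation.
Missing trend ⇒ 0 with warning; missing p or r ⇒ the (r − p) term is
dropped (trend weight effectively 1), logged.

## The synthetic world

`WorldSpec` defaults describe a mid-sized assessment: 20 regions (15%
uninhabited), years 2005–2016 (trend windows need 5 years; weekly climate
layers need a 5-year window on top of a climatology), 5 stocks and 3 grid
cells per region, heavy-tailed EEZ areas (log-normal, σ = 1.5 on the log),
observed-status panels with per-region slopes ~ N(0.2, 1.0²) points/yr and
residual SD 1, climate anomaly injection rate 2% per cell-week, 10%
missing-at-random SPI entries. A `level_slope_corr` knob couples a region's
status level to its slope so "the good get better" regimes can be switched
on in experiments; it defaults to off.

Stocks follow Schaefer dynamics toward a target terminal B/B_MSY drawn
uniformly from [0.3, 1.9] under two regimes: overfished targets (< 1) get a
prescribed smoothstep depletion path whose implied catch shows the
rise-and-fall of a collapse; under/fully-exploited targets get a developing
fishery whose harvest rate ramps to the target's equilibrium rate, giving
monotonically rising catch. (A single mechanism produces an unrealistic
history for one of the regimes — a collapse without terminal catch decline,
or a developing fishery with a spurious catch bump.) The range stops at 1.9
because at exactly 2 the equilibrium harvest rate is zero and the catch
series degenerates. Catch carries 10% lognormal observation noise; the
emitted truth is exactly 2B/K of the re-simulated trajectory. About 15% of
stocks also receive "formal assessment" values (truth × 5% lognormal
noise) to exercise the override path.

What the generator does **not** emulate: spatial autocorrelation between
cells, real-world country value distributions, reporting artefacts (unit
changes, retroactive revisions), regime shifts in pressures, and correlated
missingness. Passing recovery tests therefore demonstrates the estimators
are correct under the stated generating model, not that they are robust to
every pathology of real global reporting.

## Statistical analyses

Five-year change: per-region OLS slopes; a random-intercept mixed model
(score ~ year, region random, REML via statsmodels MixedLM, year centred;
L-BFGS with a Powell fallback for boundary fits) reporting the fixed slope,
its normal-approximation 95% CI and the random-intercept SD; EEZ-area
weighting applies only to the summary of per-region slopes, not to the REML
fit. Predictive validity: OLS of last-year score on first-year score,
realized status on predicted (likely future) status, observed change on
predicted change, and observed change on each model component, per goal,
with identity-line bias summarised by first-year score tercile; comparisons
with < 3 pairs are skipped and flagged. Ranks are descending (1 = best)
with ties broken by region_id (stable and documented); Δrank =
rank_first − rank_last so positive means improvement; a sign mismatch flags
score and rank moving in opposite directions. Index-change decomposition:
contribution_g = w_g/Σw × Δscore_g, summing exactly to ΔIndex on complete
panels; goals present in only one year force renormalisation and the
residual is reported per region. Significance is reported at two-sided
0.05 with no multiple-testing correction.

## Numerical choices and degenerate inputs

- Biomass floor K×10⁻³ in all Schaefer simulation (feasibility filtering
  needs strictly positive trajectories); crashed draws are parked at the
  floor and already marked infeasible so they cannot overflow.
- Per-stock estimator seeds derive deterministically from the panel seed
  (`seed × 1 000 003 + stock_id mod 2³¹−1`): panel runs are reproducible and
  stocks independent.
- Geometric means guard with a 10⁻¹² floor inside the log; an exact zero
  component in clean waters short-circuits to 0.
- Quantile references (99.99th) use the default linear interpolation of
  `numpy.quantile` on the empirical pool.
- A constant weekly series (SD = 0) has no anomalous weeks (strict
  inequality).
- Scores CSV round-trips at 9 significant digits (`%.9g`).

## Problem sizes

Default test and acceptance runs use 20 regions × 12 years, 100 stocks ×
5 000 draws, and 100 mixed-model replicates of 200 regions × 5 years —
sizes at which every stochastic check is stable across seeds while a full
suite completes in a few minutes on one core.

## Known limitations

- Catch-only stock assessment is prior-driven; the final-depletion window
  encodes the fishery-development narrative and misreads histories that
  violate it (e.g. a collapse followed by recovery, or effort collapse with
  a healthy stock).
- Parent-goal dimensions are weighted means of subgoal dimensions, which is
  exact for status/score but an approximation for pressure and resilience
  when subgoal weights differ.
- The likely-future-status model is multiplicative in status, so a region
  at status 0 can never be predicted to recover.
- One scenario year per invocation: method changes are not back-cast onto
  earlier years.
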