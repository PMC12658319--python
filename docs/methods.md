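# Methods

`sorgsim` simulates the growth of photoperiod-sensitive (PS) biomass sorghum
at a daily time step driven by hourly weather, and calibrates its
genotype-specific parameters from observed leaf and stem dry-biomass
trajectories. This note documents the model, its parameters and defaults,
the synthetic-data generator, the calibration algorithm, numerical choices,
and known limitations.

## The crop model

### State

A plant is a **main culm** plus zero or more **tillers**, each carrying
leaf, stem, root and grain organ pools. Every organ tracks a dry weight
(g/plant); stem and root additionally track a structural dimension (height
in m, length in m) and a reference tissue density (g per m). Two
irreversibility rules shape the state space:

* **Structural irreversibility.** Stem height and root length never
  decrease — cell expansion and lignification cannot be undone.
* **Density remobilization.** Under carbon deficit, dry matter is withdrawn
  from organ pools while dimensions are held, lowering tissue density below
  the reference; when carbon returns, density is restored to the reference
  before any new structural growth.

The plant also carries a xylem water pool (g water, bounded by a capacity)
and a labile carbon signal used for tiller initiation. The grain pool
exists but stays empty for PS genotypes in temperate runs: PS sorghum
requires daylength below a critical photoperiod (default 12 h 20 m) to
flower, which a Corn Belt summer never provides early enough to matter.

### Phenology

Development runs on two hourly accumulators:

* **GDU** (growing degree units), the hourly analogue of growing degree
  days: `max(0, min(T, T_max) − T_base) / 24` per hour. A day at constant
  temperature reproduces the classical daily GDD, while diurnal extremes
  are captured rather than averaged away.
* **GPU** (growing phenology units): a triangular normalized temperature
  response (0 at `T_base`, 1 at `T_opt`, 0 at `T_max`) times a saturating
  normalized radiation response `min(R/R_norm, 1)`, divided by 24, so one
  fully optimal day contributes 1.0 GPU. Stage thresholds are therefore in
  "optimal-day" units.

The stage machine is forward-only: planting → vegetative (at the GDU
emergence threshold) → bloom/grain-fill (at the GPU maturity threshold) →
harvest (forced on the harvest date). For PS genotypes the floral
transition is doubly gated by photoperiod: the transition requires
daylength below the critical threshold **and** GPU accumulates only on such
inductive short days. This is the classic short-day induction mechanism; at
42° N it means the autumn window between the photoperiod opening
(mid-September) and harvest (mid/late October) cannot accumulate enough GPU
to reach the default maturity threshold, so PS plants remain vegetative all
season — the behaviour observed in the field trials the model targets.
Daylength itself uses the geometric sunrise equation (solar declination →
sunrise hour angle), with no refraction or twilight correction: the
photoperiod gate is a coarse threshold and refraction shifts are
second-order.

### Daily physiology

Each day executes a fixed operator order: phenology → stress → light
interception and photosynthesis → transpiration → water balance →
maintenance and senescence → growth allocation → tillering. Hourly weather
feeds only the phenology accumulators; everything else uses daily
aggregates (mean/min/max air temperature, total shortwave radiation, mean
relative humidity and wind, summed evapotranspiration, root-zone soil
temperature as the mean of the 4- and 12-inch depths, root-zone moisture as
the mean of the 12- and 24-inch volumetric water contents).

**Stress.** Four factors in [0, 1] (1 = unstressed): air heat (piecewise
linear in the daily maximum between `heat_opt` and `heat_kill`), air cold
(daily minimum between `cold_kill` and `cold_opt`), root (cold and heat
ramps on root-zone soil temperature), and water (1 − yesterday's water
deficit). Piecewise-linear ramps with optimum/kill breakpoints are the
simplest shapes consistent with threshold-style stress biology, and every
breakpoint is calibratable.

**Photosynthesis.** Canopy interception follows Beer's law on a leaf area
index proxied by `SLA × leaf mass × stand count`; the per-plant share
divides areal interception by stand count, so crowding dilutes light
per plant. Daily assimilation is the **minimum of four capacities** —
light (radiation-use efficiency × intercepted), water (proportional to
available water), leaf source capacity (per g leaf), and phloem transport
(a flat daily cap) — scaled by the product-free minimum of the air heat and
cold stress factors. The limiting-factor minimum keeps each capacity
independently testable and identifiable.

**Water.** Uptake is `uptake_coeff × root length × soil moisture /
(1 + competition_coeff × stand count)`, capped by xylem transport capacity;
stand density competes for soil water through the denominator. Storage is a
single plant-level xylem pool clipped to its capacity. The water deficit is
the unmet fraction of transpiration demand after uptake and storage; demand
itself scales with leaf mass, Tetens vapour-pressure deficit, a linear wind
amplification and the day's reference evapotranspiration. Soil moisture is
an external input and is never depleted by the crop.

**Maintenance and senescence.** Maintenance respiration is linear in organ
weight (per-organ coefficients, tillers included). Senescence removes a
per-organ fraction proportional to how far the lowest applicable stress
factor falls below one — above-ground organs respond to the air and water
factors, roots to the root and water factors. Cold-driven leaf senescence
late in the season is the mechanism behind the earlier-harvest
recommendation in cold-October years.

**Growth and carbon accounting.** `net = assimilate − maintenance`.
Surplus becomes structure at `growth_efficiency` (growth respiration is
folded into this conversion), restoring stem/root tissue density first and
then splitting across organs by stage-specific partition fractions
(normalized to sum to 1; tiller sinks are discounted). Deficit remobilizes
dry matter at 1:1 in the order stem → root → leaf — protecting the
photosynthetic source longest — with dimensions untouched and weights
floored at zero. A small seed carbon reserve buffers maintenance deficits
until it is spent, which carries the seedling through pre-emergence days.
Per-day carbon closure (organ-weight change = structural gain −
remobilized − senesced) holds to 1e-9 relative and is asserted over random
seasons in the test suite.

**Tillering.** A tiller initiates when the plant is vegetative, thermal
time exceeds a threshold, the daily carbon surplus crosses a trigger and a
slot is free (integer cap). The new tiller is seeded by transferring a
fraction of the main culm's leaf and root mass — whole-plant dry matter is
conserved — and thereafter shares assimilate with the main culm through
the discounted allocation. Observable leaf/stem biomass is always main
culm plus tillers, matching how destructive field samples are weighed.

## The 56-parameter genotype vector

All genotype-specific behaviour is concentrated in a bounded 56-entry
vector: 7 phenology constants, 8 air/root stress breakpoints, 6
photosynthesis coefficients, 3 transpiration coefficients, 4 water-relation
constants, 4 maintenance and 4 senescence coefficients, 3 growth constants,
7 partition weights, 5 tillering constants and 5 seed/initial-state values.
Defaults take APSIM sorghum conventions where a direct analogue exists
(cardinal temperatures 11/30/42 °C, Beer-law extinction ≈ 0.55) and common
physiological magnitudes otherwise; each entry carries bounds wide enough
to span realistic cultivar variation. The exact membership of the registry
is a design choice of this package — what matters contractually is that
exactly 56 bounded, named tunables exist and that the calibrator treats
them uniformly.

Water-relation and source-capacity defaults were fixed (once, at design
time) so that the default genotype shows the density response agronomy
reports for biomass sorghum: per-plant biomass strictly decreasing with
density and areal yield peaking at an interior optimum (here ≈ 11–20
plants/m², against the 10–20 commonly reported), driven by light dilution
plus water competition. No default was adjusted against test outcomes
afterwards.

## Weather input and imputation

Hourly weather follows the Iowa Environmental Mesonet station schema (air
temperature, relative humidity, shortwave radiation, precipitation, wind,
evapotranspiration, soil temperature at 4/12/24/50 in, soil volumetric
water content at 12/24/50 in). Import validation flags unparseable and
physically out-of-range cells as missing and counts them in a report; gaps
in the timestamp axis become explicit all-missing rows.

Missing cells are filled by a k-nearest-neighbours imputer (default k = 5):
candidate neighbours are fully observed hours, distance is Euclidean over
z-scored fields observed in the target row plus sin/cos-encoded hour-of-day
and day-of-year (so 3 pm gaps are filled from other afternoons in the same
part of the season), ties break toward the earlier timestamp, and the
imputed value is the neighbour mean. This makes imputation deterministic,
idempotent, non-destructive of observed cells, and range-preserving (a
mean of observed values). The k, the feature space and the
per-cell-vs-multivariate question are open choices; the implementation
imputes all of a row's missing fields from one neighbour set.

## Calibration

The objective is **RRMSE** — root mean square error divided by the mean
observed value — computed on total (leaf + stem) dry biomass pooled over
every sampling day of every training series of a genotype. Per-organ RRMSE
is available as a diagnostic only. RRMSE is scale-invariant, which makes it
comparable across traits and years.

The tuner is a stochastic coordinate search over the bounded vector:

1. sample `n` (default 5) parameters, with probability proportional to
   local sensitivity — the larger absolute objective change under a ±2%
   -of-range probe — plus a floor (1% of the maximum sensitivity) that
   keeps every parameter reachable;
2. for each selected parameter propose the incremented and the decremented
   value at the current step size, clipped to bounds;
3. evaluate each single-coordinate proposal;
4. accept the best proposal only if it improves the incumbent.

Steps start at 10% of each bound range, halve after 50 consecutive
non-improving iterations, and floor at 0.1% of range. Sensitivities are
refreshed every 200 iterations (0 disables refresh). The search stops on an
RRMSE tolerance, a wall-clock limit, or an iteration cap — the cap is an
addition that makes tests hardware-independent. Acceptance of improvements
only makes the objective trace non-increasing by construction; all
randomness flows from one seed, so runs are bit-reproducible.

Identifiability is deliberately framed at the trajectory level: on
noise-free synthetic data the tuned simulator reproduces the generating
biomass trajectories to RRMSE ≤ 5%, but individual parameters are not
expected to be recovered — many 56-vectors produce indistinguishable
trajectories from eleven sampling days.

The cross-year protocol tunes each genotype on all of one year's series
(blocks pooled — one genotype vector per genotype, not per block) and
evaluates on the other year's series with that year's weather and
management, in both directions, plus a combined-years training run.
Genotypes lacking a year are excluded and listed.

## The synthetic-data generator

No public dataset accompanies the study design this package targets, so the
generator is first-class, tested code that emulates the trial's statistical
structure:

* **Weather**: hourly series (default Apr 1 – Dec 15) at 42° N from a
  seasonal sinusoid (mean 8.7 °C, amplitude 14.9 °C, peak day 201 — Boone,
  IA normals), a 5.5 °C diurnal cycle peaking at 3 pm, AR(1) daily
  anomalies (persistence 0.75, sd 2 °C), clear-sky solar geometry times
  autocorrelated cloudiness, humidity anti-phased with the diurnal cycle,
  rain-day coupling, depth-lagged soil temperatures and a slow soil
  moisture balance. Opt-in scripted anomalies: a −7 °C October (the
  observed cold late season of the second trial year), a heavy
  post-planting rain, and an arbitrary cold-snap window for mechanism
  tests. AR parameters were chosen so monthly mean temperature tracks the
  generating sinusoid to ±0.5 °C when averaged over ten seeds.
* **Trial design**: 265 genotypes × 2 blocks × 2 years (planting/harvest
  5/27–10/17 in 2021, 5/30–10/26 in 2022), stand counts drawn from
  N(14.56, 3.83²) plants/m² truncated positive, sampling at days 22, 36,
  43, 50, 57, 64, 71, 78, 85, 110, 145 after planting. Nominal days beyond
  the harvest day are clipped to it (2021's day 145 becomes 143), mirroring
  field sampling dates that slip by one or two days; every series has 11
  points and each year yields 530 series.
* **Observation noise**: multiplicative lognormal with CV 0.15 (mean-one),
  since biomass is positive and measurement error scales with size. The
  real error structure of destructive sampling is unknown; the CV is a
  modeling choice.
* **Genotypes**: uniform draws within the registry bounds; a `spread`
  argument shrinks the box around the bound midpoints for realistic
  central genotypes in recovery experiments.

What passing tests on these synthetics does **not** show: agreement with
real Boone trajectories, real weather covariance structure, genotype
effects beyond what the 56 parameters express, or management effects
(irrigation, fertilization, tillage) the model does not represent.

## Problem sizes used in tests and the acceptance script

Calibration experiments run at reduced scale as this package's standard
experiment design: recovery uses one 85-day season (sampling through day
78) and one block per genotype with a 2,000-iteration cap and a 5%
tolerance; the cross-year experiment uses 6–20 genotypes, one block, 60
iterations, noise CV 0.15. Scenario analyses run full seasons (1–40
plants/m² sweeps; ±3-day planting and −12..+2-day harvest grids). The
trial-count checks run the generator at full scale (265 × 2 × 2).

## Numerical choices and edge cases

* Tie-breaks: neighbour ties in imputation go to the earlier timestamp;
  proposals falling outside bounds are clipped, not rejected, preserving
  search pressure at the edges.
* Degenerate seasons: zero radiation ⇒ zero assimilation every day and
  non-increasing biomass; zero stand density is a domain error; weather
  with remaining missing values is rejected with a pointer to the imputer.
* The objective is undefined when mean observed biomass is ≤ 0 and raises.
* Partition weights are stored as free positive numbers and normalized per
  stage; the grain fraction is forced to zero for PS genotypes.
* Carbon closure tolerance is 1e-9 relative; density restoration splits
  surplus across stem/root gaps proportionally to gap size.
* All engine arithmetic is plain deterministic float; identical inputs give
  bitwise-identical traces.

## Known limitations

* No nutrient dynamics, irrigation, fertilization, tillage, pest or frost
  damage; soil water is exogenous (no crop feedback).
* Leaf area is proxied by leaf dry weight (no specific-leaf-area state
  dynamics); grain filling is a stub beyond the stage flag.
* Stress shapes, the four-capacity minimum and the remobilization order are
  structural choices; the field data that would discriminate among the
  alternatives (e.g. organ-resolved senescence rates) are not part of the
  target dataset.
* Calibrated parameters inherit the identifiability caveat above:
  trajectories, not parameters, are the recoverable object.
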