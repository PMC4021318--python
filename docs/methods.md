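# Methods

This note documents the model, the calibration machinery, the synthetic
study generator, and the numerical and design choices behind `soyco2`.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The crop model

The simulator advances one day at a time over a growing season and returns
one yield per cell-year.

**Photosynthesis.** Leaf net assimilation follows the standard
Farquhar–von Caemmerer–Berry form, `A = max(0, min(Ac, Aj) − Rd)` with the
Rubisco-limited rate `Ac = Vcmax (Ci − Γ*)/(Ci + Kc(1 + O/Ko))` and the
RuBP-regeneration-limited rate `Aj = J (Ci − Γ*)/(4Ci + 8Γ*)`.  The electron
transport rate `J` is the lower root of the non-rectangular hyperbola in
absorbed PAR with curvature θ = 0.9 and quantum yield φ = 0.3 (electron per
photon basis).  Dark respiration is `Rd = 0.015 · Vcmax`.  Kinetic constants
at 25 °C (Kc = 404.9 µmol mol⁻¹, Ko = 278.4 mbar, Γ* = 42.75 µmol mol⁻¹,
O = 210 mbar) scale with leaf temperature by Arrhenius factors using widely
used activation energies (Vcmax 65.33, Jmax 43.54, Kc 79.43, Ko 36.38,
Γ* 37.83 kJ mol⁻¹).  No high-temperature deactivation is modelled, so the
temperature response is monotone over the simulated range.

**Intercellular CO₂.** `Ci = 0.7 · Ca`, constant.  This is the simplest
defensible stomatal coupling; its consequence — that elevated CO₂ does *not*
feed back on soil moisture through reduced stomatal conductance — matters
for the spatial statistics (see Limitations).

**Canopy and daily integration.** The canopy is one big leaf: daily canopy
assimilation = leaf-level `A` evaluated at the mean daytime incident PAR
(0.48 × shortwave, 4.57 µmol J⁻¹, spread over the astronomical daylength)
× the Beer's-law absorbed fraction `1 − exp(−k·LAI)` with k = 0.5
× daylength in seconds × the drought and cold multipliers.  Carbon converts
to biomass at 30/44 g CH₂O per g CO₂ times a growth efficiency of 0.7.
Half of each day's gain goes to leaves (LAI = SLA × leaf biomass,
SLA = 0.02 m² g⁻¹) until 60 % of the thermal time to maturity has elapsed.

**Phenology.** Planting on day-of-year 135 (northern hemisphere) or 315
(southern, harvest assigned to the following calendar year); growing degree
days accumulate above 10 °C; maturity at 1500 °C·d or after at most 200
days.  All values are conventional for soybean and configurable.

**Soil water.** A single bucket of capacity `awc` = 150 mm, initialized half
full at planting.  Rainfall partitions into SCS curve-number runoff
(CN = 75) and infiltration; evaporative demand is Hargreaves from the
diurnal temperature range and top-of-atmosphere radiation, drawn down in
proportion to relative storage; excess above capacity drains.  The balance
closes exactly by construction, and a test checks 1e-9 mm closure over full
seasons.  Drought stress is `(s/awc)^drought_sens`; cold stress is
`max(0, 1 − cold_sens · max(0, threshold − tmean))` applied to assimilation
(whether cold acts on photosynthesis or yield formation is an open choice;
a daily multiplier on assimilation was adopted).

**Yield.** `yield = yield_scale × final aboveground biomass × 0.01 +
tech_intercept + tech_slope × (year − 1980)`, floored at zero.  The additive
linear technology term absorbs cultivar and management progress and cancels
exactly in counterfactual differences.

**Calibrated parameters (7 per cell).** `co2_sens` (multiplies Vcmax25 and
Jmax25 jointly; carries down-regulation uncertainty of the CO₂ response),
`tech_intercept` (t/ha), `tech_slope` (t/ha yr⁻¹), `drought_sens`,
`cold_threshold` (°C), `cold_sens`, `yield_scale`.  An eighth nuisance
dimension, the yield error SD σ, gets a Jeffreys-like 1/σ prior on
[0.01, 2] t/ha; "seven parameters" counts the physical ones only.

## Two-stage Bayesian calibration

**Stage 1 — FACE.** Vcmax25, Jmax25, SLA and growth efficiency are fitted to
aboveground and leaf biomass time courses at ambient and elevated CO₂ with
independent Gaussian errors at each observation's SD, using simulated
tempering (defaults: 200 000 steps, 20 temperatures geometric from T = 1 to
T = 50).  Posterior means are frozen into the physiological constants for
stage 2.  These four dimensions are strongly ridge-correlated given biomass
data alone, so stage 1 is judged by posterior-predictive trajectory error
rather than marginal recovery.

**Stage 2 — per cell.** The 7 + 1 parameters are updated against the cell's
yield series (diagonal multivariate normal likelihood, i.e. independent
years) with DREAM (defaults: 50 000 generations, 10 chains).  Each cell is
independent.

**Simulated tempering details.** The chain moves on (θ, k) with stationary
density ∝ exp(lp(θ)/T_k − ζ_k).  During burn-in (first 50 %) the pseudo-prior
weights ζ_k are estimated via the stepping-stone identity
`ζ_{k+1} − ζ_k = log E_k[exp((1/T_{k+1} − 1/T_k)(lp − lp_ref))]`, tempering
relative to the best log-posterior seen (`lp_ref`) so ladder moves respond to
O(dim) fluctuations rather than the absolute size of lp.  At freeze the
weights get a geometric tilt (occupancy ∝ 0.8^k) so the unit-temperature
level is visited often; the conditional law of θ at T = 1 is the exact
target regardless of the weights.  Ladder moves (±1 level, proposal
probability 0.1) and within-level Gaussian random-walk steps (scale ∝ √T,
Robbins–Monro adapted toward 30 % acceptance during burn-in) are both plain
Metropolis accepts, so the frozen chain is reversible — verified empirically
by transition-flux symmetry on a three-state toy target.

**DREAM details.** Proposals are scaled differences of two randomly chosen
other chains restricted to a random crossover subspace (3 crossover values
with probabilities adapted from normalized jump distances during burn-in),
jump rate γ = 2.38/√(2d′) with a 20 % chance of γ = 1 for mode swaps, ±5 %
multiplicative jitter and 1e-6 additive noise.  Outlier chains (mean
log-posterior below Q1 − 2·IQR) are reset to the best chain during burn-in
only.  All post-burn-in states of all chains are retained; Gelman–Rubin
R-hat is available as a diagnostic.

**Priors** (the "realistic bounds"): co2_sens ~ LogNormal(0, 0.25²);
tech_intercept ~ U(−2, 2); tech_slope ~ N(0.02, 0.02²) truncated to
[−0.05, 0.1]; drought_sens ~ U(0, 3); cold_threshold ~ U(0, 15) °C;
cold_sens ~ U(0, 0.5); yield_scale ~ U(0.1, 0.6).  All configurable.

## Counterfactual attribution

For each retained draw (thinned on an even deterministic grid, default ≤200
draws) the cell is simulated over the evaluation window (2002–2006) under
historical CO₂ and under CO₂ fixed at 339 ppm (the 1980 level; one passage
of the source material says 338 ppm — 339 is the default and the value is an
argument).  Weather, parameters and technology terms are shared, so the
paired difference isolates the CO₂ response; percentages are relative to the
counterfactual mean by default (`pct_base="factual"` switches the
convention).  Climate-trend effects replace the fixed-CO₂ run with a run in
which one forcing variable is linearly detrended to its 1980 level (OLS
slope of the growing-season annual mean; precipitation and radiation floored
at zero; tmin/tmean/tmax shifted together).  Country averages are unweighted
across eligible cells, with an optional weight mapping.

## Spatial statistics

Thornthwaite PET uses the classic heat-index formulation with the
daylength/month-length correction (an uncorrected variant exists for
closed-form checks); growing-season P:PET sums daily precipitation and
uniformly day-spread monthly PET over a 150-day window from planting.
Kendall's τ-b comes from scipy, with exact enumeration p-values for n ≤ 8
without ties.  The effect-vs-P:PET inflection is located by fitting three
models — (1) a line, (2) two intersecting sloped lines, (3) a flat segment
meeting a sloped one — with the breakpoint profiled over all observed x
values below the maximum plus 100 equispaced interior candidates (including
the minimum, so models 2/3 nest model 1 exactly); ties go to the smallest
breakpoint.  AIC = n·ln(RSS/n) + 2k, with k counting the breakpoint and the
error variance (3/5/4 for models 1/2/3) and the RSS floored near the
double-precision resolution of the response so exact fits compare as ties.
Model selection treats fits within 2 AIC units of the minimum as equivalently
supported and picks the most parsimonious (`tie_tol=0` restores a strict
argmin); under a strict argmin a one-extra-parameter rival is preferred with
probability ≈ P(χ²₁ > 2) ≈ 16 % even when the smaller model is true, which
no noise level changes, so the equivalence band is what makes high selection
rates for the true model attainable.

## The synthetic-data generator

The generator emulates the *structure* of the study inputs with known ground
truth.  Defaults are the study conditions: years 1980–2006, a linear CO₂
ramp 339 → 377 ppm, yield noise SD 0.3 t/ha, harvest-area fraction 0.05.
Weather is a sinusoidal seasonal temperature cycle per cell archetype
(country-specific annual means/amplitudes; southern-hemisphere phase for
Brazil) with AR(1) daily anomalies (ρ = 0.7, sd 1.5 °C) and Gaussian yearly
offsets (sd 0.5 °C); rainfall is Bernoulli–Gamma with a warm-season wet bias,
a per-cell aridity multiplier spread over [0.45, 1.4] (so P:PET varies across
the grid) and a lognormal yearly wetness factor (drought years); radiation is
top-of-atmosphere times a transmissivity of 0.70 (dry) / 0.40 (wet days).
True per-cell parameters are drawn once from moderately narrower
"realistic" ranges inside the prior supports (e.g. yield_scale U(0.2, 0.5),
co2_sens LogNormal(0, 0.15²), tech_slope ≥ 0), so generated cells are
agronomically plausible while coverage tests remain meaningful.  FACE data
are one stress-free season at 372/552 ppm observed every 14 days with a 5 %
(floored at 5 g m⁻²) reported SD.

**What passing tests show, and what they do not.**  The generator shares the
crop model with the estimator, so recovery tests validate the inference
machinery and the attribution arithmetic — not the model's fidelity to real
soybean systems.  Real yield records contain spatially correlated errors,
management shocks, pest outbreaks and reporting changes that the independent
Gaussian noise does not emulate; real weather has spatial covariance and
trends that the generator omits by design (its climate is trendless, which
is what makes the climate-trend machinery testable against a zero).

## Numerical choices

- All heavy per-day arithmetic runs through numba-jitted kernels; the scalar
  `grow_day`/`simulate_season` path is the readable reference and a test
  pins both paths together to 1e-9.
- Per-cell forcing (temperature kinetics, PAR, the soil-water trajectory,
  phenology masks) is precomputed once; it is parameter-independent because
  ET demand does not depend on crop state and phenology depends only on
  temperature.  One 27-year likelihood evaluation costs ~0.2 ms.
- Degenerate inputs: `Ci < Γ*` clips assimilation at zero; zero daylength or
  zero radiation contributes nothing; `0^0 = 1` gives the drought multiplier
  identity at zero sensitivity; sampler initialization redraws from the
  prior up to 100 times before failing.
- Determinism: every stochastic component takes an explicit seed; posterior
  thinning uses an even index grid, not resampling.  Fixed seed ⇒
  bit-identical samples.

## Reduced problem sizes

The validation experiments use scaled-down MCMC budgets chosen as the
package's own defaults for desk-scale studies: 5000 DREAM generations × 5
chains per cell in the 20-cell recovery study, and 20 000 tempering steps ×
10 temperatures for the FACE stage in the reproduction script.  The
full-scale defaults (50 000 × 10 and 200 000 × 20) remain the documented
settings for production runs.

## Known limitations

- No stomatal-conductance response to CO₂: in the field, elevated CO₂
  reduces transpiration and spares soil water, amplifying the fertilization
  effect precisely where water is scarce.  With `Ci = 0.7·Ca` fixed and
  drought independent of CO₂, this channel is absent, so on synthetic grids
  the percentage effect tends to *increase* with P:PET (wetter cells grow
  more and sit higher on the response curve) — the opposite sign of the
  dryness correlation reported for real data.  The Kendall statistics the
  package computes are therefore structural diagnostics, not reproductions.
- Simulated percentage effects (≈8–15 % for +38 ppm) sit above the naive
  linear FACE extrapolation (≈3 %) because biomass compounds: an early-season
  assimilation gain grows more leaf area, which absorbs more light.  The
  compounding is strongest in open canopies (low LAI), consistent with the
  Beer's-law arithmetic in the README.
- No nitrogen dynamics, allocation schemes beyond the fixed leaf split,
  insect damage, photosynthetic acclimation, or senescence; biomass is
  non-decreasing within a season.
- Thermal-time phenology means imposed warming can shorten the season and
  reduce yields even in cool cells; warming helps only where cold stress
  dominates and the season is window-capped.
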