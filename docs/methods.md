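# Methods

This note documents the models implemented in `standcarbon`, the defaults and
numerical choices, what the synthetic study system does and does not emulate,
and the known limitations. Units throughout: diameters cm, heights m, dry
biomass Mg ha⁻¹ (kg for a single tree), carbon Mg C ha⁻¹, rates yr⁻¹.

## Estimator structure

The quantity of interest is the annualised 15-year carbon change per pool and
stand. All pools are estimated indirectly — stocks are predicted at the two
survey epochs and differenced — and all inference is model-based: the
uncertainty statements derive from the fitted models' coefficient
distributions, not from a design-based sample. Five models carry estimated
parameter covariance (the area-based biomass, dominant height, mean height
and diameter regressions, and the allometric component set); growth models,
turnover fractions, chemical partitions and the carbon fraction (0.5) are
treated as fixed constants with unaccounted uncertainty.

### Area-based models

Fixed functional forms (see README) fitted by OLS on the pooled two-epoch
plot sample with an epoch dummy T, giving time-invariant structure. Log-scale
responses (diameter, biomass) are back-transformed by plain exponentiation;
no lognormal bias correction is applied by default because the chain is
calibrated end to end against synthetic truth generated the same way. A
correction flag exists on both the allometric and area-model sets.
A subset-selection routine (exhaustive BIC minimisation with
`BIC = n ln(RSS/n) + p ln n`, at most five parameters including the
intercept, maximum variance inflation factor 5, T always retained) documents
how such forms are derived; the pipeline itself uses the fixed printed forms.
Predictions are floored at D ≥ 0.1 cm, H ≥ 1.3 m, BMS ≥ 0, and mean height
is capped at the predicted dominant height.

Canopy metrics: percentiles use linear interpolation between order
statistics; density levels are ten equally spaced heights from 1.3 m to the
95th percentile of the returns above 1.3 m, and densities are proportions of
those canopy returns strictly above each level. Cells whose returns all fall
below 1.3 m produce an all-zero sentinel record.

### Allometry

Marklund-form models per species × component, fitted by OLS on the log scale
with classical covariance σ̂²(XᵀX)⁻¹. Birch has no stump/foliage/root
observations: its stump model delegates to pine, and foliage / fine roots /
coarse roots are fixed ratios of predicted stem wood (0.011/0.52 and
0.042/0.52). The birch branch column is branches-plus-foliage; by default it
counts once in above-ground totals and the ratio-derived foliage is used only
where litter chemistry needs a foliage mass, avoiding double counting. The
other reading (foliage delegated) is available through the model-set flags.

### Growth and the disturbance scenario

A cell is disturbed when its predicted biomass decreased between the epochs;
the event year comes from the disturbance map, else the floored midpoint
(2008). The pre-event tree is grown forward from the first epoch and the
post-event tree reconstructed from the second epoch by inverting the growth
model with recursive interval halving (tolerance 10⁻³ in each variable's
native unit — cm for D, m for Hdom; dominant height first, since its
increment depends only on site index and age, then diameter). Stand age at
the first epoch is map age minus 17 (map year 2018), floored at 1.

The bundled growth family is deliberately simple and closed-form, with the
semigroup property (growing 5+5 years equals 10) and monotonicity that the
inversion requires:

    Hdom' = Hdom + h₁·SI·(φ(AGE+y) − φ(AGE)),  φ(a) = 1 − e^(−λa)
    D'    = D·((1+AGE+y)/(1+AGE))^c,           c = c₀·(SI/14)·(n₀/(n₀+N))

with per-species (h₁, λ, c₀) defaults and n₀ = 1000. Any object implementing
`grow`/`grow_arrays` can be registered instead; published regional growth
models drop in through that interface.

### Litter

Turnover sheds a fixed annual fraction of each standing component; mortality
transfers whole trees at rate m = 1 − (N₂₀₁₆/N₂₀₀₁)^(1/15) when stems
decline, else the constant 0.4 % yr⁻¹ (disturbed cells also use the constant
— their stem loss is attributed to harvest; a policy flag switches this);
harvest, in the event year only, transfers everything removed except 95 % of
the removed stem wood. Annual inputs are linear interpolations between the
anchor litters (two anchors undisturbed, four disturbed, with the harvest
spike added in the event year). Carbon is 0.5 × dry mass, split over the
A/W/E/N compartments by species- and component-specific chemistry rows that
must sum to one exactly.

The bundled turnover fractions and chemical partitions are defaults drawn
from the range used for boreal conifers and birch in the soil-model
literature (e.g. foliage 0.139/0.278/0.79 yr⁻¹ for spruce/pine/birch, fine
roots 0.85, branches ~0.013–0.027, foliage-like chemistry for fine roots,
woody chemistry (0.72, 0.03, 0.08, 0.17) elsewhere). They are configuration
data, loadable from the run configuration, and nothing in the package depends
on these exact values.

### Soil model

A linear five-compartment system (A, W, E, N, humus) in which each litter
compartment decomposes at a climate-modulated first-order rate, the outflow
splitting into transfers to other litter compartments, humification, and CO₂;
humus only emits CO₂. The within-year dynamics dx/dt = Mx + u (constant
annual input) are advanced exactly with a matrix exponential; the one-year
transition pair (P, R) comes from a single 10×10 augmented exponential, which
remains valid when M is singular (zero climate modifier). Linearity is what
makes cohort tracing exact, and it is enforced by tests at the 10⁻¹⁰ level.

The climate modifier multiplies all rates:
ξ = mean over 12 months of exp(b₁T_m + b₂T_m²) × (1 − e^(−gP)), with
T_m = T + (amplitude/2)·sin(2πm/12), b₁ = 0.09 °C⁻¹, b₂ = −0.0013 °C⁻²,
g = 1.2 m⁻¹ and P in metres. The monthly average captures the convexity
benefit of seasonal temperature variation using the annual amplitude
variable; the precipitation response saturates. Default potential rates
(0.42, 1.20, 0.50, 0.050 yr⁻¹ for A/W/E/N; 0.0050 for humus), sparse
transfer fractions and a uniform 4.5 % humification were chosen so that
per-(species, site index) equilibria land on the same order as the bundled
long-term reference table; they are structural placeholders for a calibrated
parameter set, loadable from configuration, and the uncertainty module
accepts an external parameter sample table in place of the synthesised one.

Legacy ("old") carbon at the first epoch is initialised in two stages: a
long-term equilibrium per species × site index (bundled reference CSV, or
spun up from a reference litter input), then a reconstruction of the current
silvicultural cycle — from a clear cut AGE years before the epoch, starting
at that equilibrium, with annual litter ramped linearly from 0 to the cell's
first-epoch level. The resulting state splits into an AWEN cohort ("old
litter") and a humus cohort ("old SO") that are traced through the timeframe
with no input. Spin-up is computed in closed form, x* = (I−P)⁻¹Rq, and
cross-checked by iteration; because the humus compartment contracts by only
~0.3 % per year, the iteration continues until the per-step increment falls
below 10⁻¹¹ (bounding the geometric tail well under the 10⁻⁸ state
tolerance) before the two routes are compared at 10⁻⁶.

### Pools

AGB and BGB carbon are 0.5 × BMS split by the mean tree's component
proportions (the area-based biomass acts as the scale factor; AGB + BGB
= 0.5 × BMS exactly). The litter pool is the A+W+E+N of the turnover+harvest
cohort, deadwood the A+W+E+N of the mortality cohort, and SO the humus of
both. The legacy-inclusive variant merges deadwood into litter and adds the
old cohorts to both sides of the difference. Within-timeframe cohorts start
from zero, so their "change" is accumulation; the legacy-inclusive variant is
the net balance.

### Uncertainty

Parametric bootstrap: each draw samples every model group's coefficients from
N(β̂, Σ̂) (each allometric model jointly within its own covariance,
independently across models), one soil parameter vector from the sample
table, and re-runs the entire chain; SEs are bootstrap standard deviations,
CIs are estimate ± 2 SE, and a stand's change is significant when its CI
excludes zero. Each model group consumes an independent random stream seeded
by (seed, group index), so one-model-at-a-time attribution runs reuse exactly
the draws of the full run for that group; shares are reported as SE_group /
SE_total × 100 per pool and deliberately do not sum to 100 % (model
interaction). Residual (within-model) error and its spatial covariance are
excluded by design. Degenerate bootstrap distributions (all outcomes
identical) report SE exactly 0 rather than summation round-off. Relative-SE
summaries filter values above the 99th percentile before averaging, since
SE% explodes where the point change is near zero. Default B = 1000 for a
production run; the bundled study and acceptance script use B = 100, which
puts the Monte Carlo error of an SE near 7 %.

## The synthetic study system

The generator produces a landscape whose default conditions mirror the kind
of inventory the estimator targets: ~520 stands of 4–16 cells (≈5 000–6 000
cells, cell side 15.26 m), species mix 55/33/12 spruce/pine/birch, site
indices 8–20, stand ages 25–120 at the 2018 map year, 116 field plots
measured at both epochs (232 design rows), a 1281-tree allometry dataset
with the reference per-component availability pattern (birch lacking
stump/foliage/root measurements), a 15.7 % target disturbed-area share, and
a 1957–2016 boreal climate series whose 1957–2000 window (44 years,
inclusive endpoints, configurable) supplies the reference climate.

Truth is constructed so that exactness is testable: a latent site-index- and
age-driven growth process (logistic stock, saturating height) drives
noise-free canopy metrics through fixed monotone maps, and the truth fields
D, Hdom, H, BMS are *defined* by the generating area-model forms applied to
those metrics, with N = BMS / mean-tree mass under the generating allometry.
Measurement noise perturbs the two latent drivers (preserving the metric
ordering invariants for every seed) and residual noise the field values, so
with all noise at zero an OLS refit recovers the generating coefficients to
machine precision and the pipeline reproduces the recorded truth.
Disturbance events remove 40–75 % of the latent stock (eligibility restricted
to stocked cells, selection probability rescaled to keep the expected
fraction), mildly lower the top height, and are kept only where the truth
biomass actually decreases — matching the detection rule the estimator uses.

What passing tests show: the chain is internally consistent (mass balance,
cohort additivity, equilibrium, scaling contracts), recovers known parameters
and truth under its own generating assumptions, and propagates parameter
uncertainty correctly (delta-method and additivity oracles). What they do not
show: accuracy under real canopy physics (the metrics are simulated
summaries, not point clouds), real growth dynamics, spatially correlated
residuals, or calibrated decomposition — all of which enter a real
application through the swappable constants and model interfaces.

## Problem sizes and runtime

The test suite runs a 520-stand / ≈5 700-cell zero-noise landscape for the
end-to-end checks (about a second for the full chain; the engine is
vectorised over cells, with per-year soil transition operators shared across
cells and legacy-cycle operators cached per stand age), 200-replicate
coverage studies for the fitted models, and B = 2000 bootstrap oracles.
The acceptance script's full study with B = 100 completes in well under a
minute on one CPU.

## Known limitations

- The bundled soil parameters, turnover fractions and chemistry rows are
  literature-range defaults, not a calibrated set; absolute soil-pool levels
  are therefore indicative only, while the structural properties (linearity,
  balance, cohort separation) are exact.
- The default growth family is a stylised stand-in with the right qualitative
  behaviour; regional growth models should replace it in applications.
- Mean height is capped at predicted dominant height and floors guard
  degenerate cells; these affect only pathological inputs.
- One soil-parameter draw per chain draw couples the soil stream to the
  regression streams only through the shared master seed; cross-model
  parameter correlation is assumed zero.
- The old-carbon initialisation inherits the long-term table's coarseness;
  the legacy-inclusive change estimates are correspondingly sensitive to it.
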